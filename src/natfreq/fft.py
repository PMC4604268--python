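"""Fast-and-frugal classification trees induced from case-level data.

A fast-and-frugal tree (FFT) asks one cue per level and offers an exit —
a final classification — at every level; only the last level has two
exits.  It is the radical pruning of a full outcome tree (a cue-first
natural frequency tree with the outcome at the leaves): instead of keeping
counts for every cue-value combination, each level commits to a decision
for one of its two branches and passes the rest on.

Induction follows the ZigZag recipe: the first k levels exit on the
positive cue value toward the positive outcome, where k is the smallest
natural number with 1/2**k below the positive/negative base-rate odds;
after level k, exits alternate negative/positive.  Cues are ranked by
predictive values (ZigZag-val: PPV for positive-exit levels, NPV for
negative-exit levels) or by sensitivity/specificity (ZigZag-sens).  Ties
are broken by a seeded random draw.

Also here: exhaustive exit-structure enumeration for ROC points, and a
naive-Bayes comparator that multiplies per-cue likelihood ratios under
conditional independence.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, MalformedInputError, UndefinedPosteriorError
from .task import NaturalFrequencyTree, TreeLayer

OUTCOME = "outcome"


@dataclass
class CaseDataset:
    """Individual records of categorical cue values plus a two-label outcome.

    ``df`` holds one row per case with the cue columns and an ``outcome``
    column.  ``positive_values`` declares which category of each cue counts
    as "positive" (cue present); no polarity is ever inferred from the data.
    ``positive_outcome`` names the outcome label playing the role of the
    condition being diagnosed.
    """

    df: pd.DataFrame
    cue_names: tuple[str, ...]
    categories: dict[str, tuple[str, ...]]
    positive_values: dict[str, str]
    positive_outcome: str

    def __post_init__(self):
        if len(self.df) < 1:
            raise DomainError("dataset must contain at least one record")
        missing = [c for c in self.cue_names if c not in self.df.columns]
        if missing or OUTCOME not in self.df.columns:
            raise DomainError(f"dataset missing columns: {missing + ([OUTCOME] if OUTCOME not in self.df.columns else [])}")
        if self.df[OUTCOME].isna().any():
            raise DomainError("dataset has records with missing outcome")
        for cue in self.cue_names:
            cats = set(self.categories.get(cue, ()))
            bad = set(self.df[cue].unique()) - cats
            if bad:
                raise DomainError(f"cue {cue!r}: values {sorted(bad)} outside declared categories")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def outcome_labels(self) -> tuple[str, ...]:
        labels = list(dict.fromkeys(self.df[OUTCOME]))
        if self.positive_outcome in labels:
            labels.remove(self.positive_outcome)
        return (self.positive_outcome, *labels)

    def negative_outcome(self) -> str:
        others = [l for l in self.outcome_labels if l != self.positive_outcome]
        if len(others) != 1:
            raise DomainError("dataset outcome space is not two-label")
        return others[0]

    def is_binary(self, cue: str) -> bool:
        return len(self.categories[cue]) == 2

    def to_csv(self) -> str:
        cols = list(self.cue_names) + [OUTCOME]
        return self.df[cols].to_csv(index=False)

    def sidecar_json(self) -> str:
        return json.dumps(
            {
                "categories": {c: list(v) for c, v in self.categories.items()},
                "positive_values": dict(self.positive_values),
                "positive_outcome": self.positive_outcome,
            },
            indent=2,
        )

    @classmethod
    def from_csv(cls, text: str, sidecar: str | None = None) -> "CaseDataset":
        from io import StringIO

        try:
            df = pd.read_csv(StringIO(text), dtype=str)
        except Exception as exc:
            raise MalformedInputError(f"invalid CSV: {exc}") from exc
        if OUTCOME not in df.columns:
            raise MalformedInputError("CSV must have an 'outcome' column")
        cue_names = tuple(c for c in df.columns if c != OUTCOME)
        if sidecar:
            try:
                meta = json.loads(sidecar)
            except json.JSONDecodeError as exc:
                raise MalformedInputError(f"invalid sidecar JSON: {exc}") from exc
            categories = {c: tuple(v) for c, v in meta.get("categories", {}).items()}
            positive_values = dict(meta.get("positive_values", {}))
            positive_outcome = meta.get("positive_outcome")
        else:
            categories, positive_values, positive_outcome = {}, {}, None
        for cue in cue_names:
            if cue not in categories:
                categories[cue] = tuple(sorted(df[cue].unique()))
        if positive_outcome is None:
            positive_outcome = sorted(df[OUTCOME].unique())[0]
        return cls(
            df=df,
            cue_names=cue_names,
            categories=categories,
            positive_values=positive_values,
            positive_outcome=positive_outcome,
        )


@dataclass(frozen=True)
class CueStatistics:
    """Sensitivity, specificity, PPV and NPV of one binary cue on a dataset.

    Each statistic is an exact Fraction, or None when its denominator is 0
    (e.g. PPV with no cue-positive cases).
    """

    sensitivity: Fraction | None
    specificity: Fraction | None
    ppv: Fraction | None
    npv: Fraction | None


def cue_statistics(data: CaseDataset, cue: str) -> CueStatistics:
    if cue not in data.cue_names:
        raise DomainError(f"unknown cue {cue!r}")
    if not data.is_binary(cue):
        raise DomainError(f"cue {cue!r} is not binary")
    if cue not in data.positive_values:
        raise DomainError(f"cue {cue!r} has no declared positive value")
    pos_val = data.positive_values[cue]
    cue_pos = data.df[cue] == pos_val
    out_pos = data.df[OUTCOME] == data.positive_outcome

    def ratio(num: int, den: int) -> Fraction | None:
        return Fraction(num, den) if den else None

    return CueStatistics(
        sensitivity=ratio(int((cue_pos & out_pos).sum()), int(out_pos.sum())),
        specificity=ratio(int((~cue_pos & ~out_pos).sum()), int((~out_pos).sum())),
        ppv=ratio(int((cue_pos & out_pos).sum()), int(cue_pos.sum())),
        npv=ratio(int((~cue_pos & ~out_pos).sum()), int((~cue_pos).sum())),
    )


def build_outcome_tree(data: CaseDataset, cue_order: Sequence[str]) -> NaturalFrequencyTree:
    """Tally the dataset into a cue-first natural frequency tree.

    Layers partition by cue values in the given order, the final layer by
    outcome; node counts are record counts, so the leaves sum to the
    dataset size.
    """
    for cue in cue_order:
        if cue not in data.cue_names:
            raise DomainError(f"unknown cue {cue!r}")
    layers = [TreeLayer(on=c, categories=data.categories[c]) for c in cue_order]
    layers.append(TreeLayer(on=OUTCOME, categories=data.outcome_labels))
    nodes: dict[tuple[str, ...], int] = {(): data.n}
    cols = list(cue_order) + [OUTCOME]
    for depth in range(1, len(cols) + 1):
        counts = data.df.groupby(cols[:depth], sort=False, observed=True).size()
        for key, count in counts.items():
            path = key if isinstance(key, tuple) else (key,)
            nodes[tuple(path)] = int(count)
    # fill in empty branches with explicit zeros so children always sum to parents
    frontier = [()]
    for layer in layers:
        new_frontier = []
        for parent in frontier:
            for cat in layer.categories:
                path = parent + (cat,)
                nodes.setdefault(path, 0)
                new_frontier.append(path)
        frontier = new_frontier
    return NaturalFrequencyTree(
        orientation="cue-first", root_count=data.n, layers=tuple(layers), nodes=nodes
    )


# ---------------------------------------------------------------------------
# fast-and-frugal trees

@dataclass(frozen=True)
class FFTLevel:
    """One non-final tree level: exit with ``exit_label`` when the cue shows ``exit_value``."""

    cue: str
    exit_value: str
    exit_label: str


@dataclass(frozen=True)
class FastFrugalTree:
    """An ordered sequence of one-exit levels plus a final two-exit level.

    ``final_labels`` maps the final cue's categories to outcome labels;
    values outside the mapping (e.g. an "unknown" category) fall back to
    ``final_default``.
    """

    levels: tuple[FFTLevel, ...]
    final_cue: str
    final_labels: Mapping[str, str]
    final_default: str
    k: int

    @property
    def cues(self) -> tuple[str, ...]:
        return tuple(l.cue for l in self.levels) + (self.final_cue,)

    @property
    def depth(self) -> int:
        return len(self.levels) + 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "levels": [
                    {"cue": l.cue, "exit_value": l.exit_value, "exit_label": l.exit_label}
                    for l in self.levels
                ],
                "final_cue": self.final_cue,
                "final_labels": dict(self.final_labels),
                "final_default": self.final_default,
                "k": self.k,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FastFrugalTree":
        try:
            doc = json.loads(text)
            return cls(
                levels=tuple(
                    FFTLevel(cue=l["cue"], exit_value=l["exit_value"], exit_label=l["exit_label"])
                    for l in doc["levels"]
                ),
                final_cue=doc["final_cue"],
                final_labels=dict(doc["final_labels"]),
                final_default=doc["final_default"],
                k=int(doc["k"]),
            )
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise MalformedInputError(f"invalid tree JSON: {exc}") from exc


def base_rate_exit_depth(n_positive: int, n_negative: int, n_levels: int) -> int:
    """k: smallest natural number with 1/2**k below the base-rate odds.

    The odds are positive/negative base rate; k is capped at the number of
    levels.  (The final level keeps both exits in any case — reaching it
    without exiting forces a decision on its cue value.)
    """
    if n_positive == 0 or n_negative == 0:
        raise DomainError("base-rate ratio undefined: only one outcome present")
    ratio = Fraction(n_positive, n_negative)
    k = 1
    while Fraction(1, 2**k) >= ratio:
        k += 1
    return min(k, max(1, n_levels))


def _rank_key(stat: Fraction | None) -> tuple[int, Fraction]:
    # undefined statistics rank below every defined one
    return (1, stat) if stat is not None else (0, Fraction(0))


def zigzag_fft(data: CaseDataset, variant: str = "val", seed: int = 0) -> FastFrugalTree:
    """Induce a fast-and-frugal tree with the ZigZag recipe.

    Levels 1..k exit on the positive cue value toward the positive outcome,
    with cues ranked descending by PPV (``variant="val"``) or sensitivity
    (``variant="sens"``).  Later levels alternate negative/positive exits,
    each time taking the remaining cue with the greatest NPV or PPV (val) /
    specificity or sensitivity (sens).  Ties are broken by a seeded draw.

    If the positive outcome is the majority class, outcome labels are
    swapped internally so the rarer class plays the positive role.
    """
    if variant not in ("val", "sens"):
        raise DomainError(f"unknown variant {variant!r}")
    cues = [c for c in data.cue_names if data.is_binary(c)]
    if not cues:
        raise DomainError("no binary cues available")
    n_pos = int((data.df[OUTCOME] == data.positive_outcome).sum())
    n_neg = data.n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DomainError("base-rate ratio undefined: only one outcome present")
    pos_label, neg_label = data.positive_outcome, data.negative_outcome()
    if n_pos > n_neg:
        pos_label, neg_label = neg_label, pos_label
        n_pos, n_neg = n_neg, n_pos
        data = CaseDataset(
            df=data.df,
            cue_names=data.cue_names,
            categories=data.categories,
            positive_values=data.positive_values,
            positive_outcome=pos_label,
        )

    L = len(cues)
    k = base_rate_exit_depth(n_pos, n_neg, L)
    stats = {c: cue_statistics(data, c) for c in cues}
    rng = np.random.default_rng(seed)

    def pick(remaining: list[str], stat_name: str) -> str:
        keyed = [(c, _rank_key(getattr(stats[c], stat_name))) for c in remaining]
        best = max(k for _, k in keyed)
        tied = [c for c, key in keyed if key == best]
        if len(tied) == 1:
            return tied[0]
        return tied[int(rng.integers(len(tied)))]

    pos_stat = "ppv" if variant == "val" else "sensitivity"
    neg_stat = "npv" if variant == "val" else "specificity"

    remaining = list(cues)
    levels: list[FFTLevel] = []
    sides: list[str] = []  # exit side per level, final level included
    for level_index in range(L):
        if level_index < k:
            side = "positive"
        else:
            # alternation starts with a negative exit after the k positive ones
            side = "negative" if (level_index - k) % 2 == 0 else "positive"
        sides.append(side)
        cue = pick(remaining, pos_stat if side == "positive" else neg_stat)
        remaining.remove(cue)
        if level_index < L - 1:
            pos_val = data.positive_values[cue]
            neg_val = next(v for v in data.categories[cue] if v != pos_val)
            if side == "positive":
                levels.append(FFTLevel(cue=cue, exit_value=pos_val, exit_label=pos_label))
            else:
                levels.append(FFTLevel(cue=cue, exit_value=neg_val, exit_label=neg_label))
        else:
            pos_val = data.positive_values[cue]
            neg_val = next(v for v in data.categories[cue] if v != pos_val)
            final_cue = cue
            final_labels = {pos_val: pos_label, neg_val: neg_label}
    return FastFrugalTree(
        levels=tuple(levels),
        final_cue=final_cue,
        final_labels=final_labels,
        final_default=neg_label,
        k=k,
    )


def classify_case(tree: FastFrugalTree, case: Mapping[str, str]) -> tuple[str, int]:
    """Walk the tree on one case; return (assigned label, cues inspected).

    Categories that match no exit value (e.g. "unknown") simply pass the
    case to the next level; at the final level they take ``final_default``.
    """
    inspected = 0
    for level in tree.levels:
        if level.cue not in case:
            raise DomainError(f"case is missing a value for cue {level.cue!r}")
        inspected += 1
        if case[level.cue] == level.exit_value:
            return level.exit_label, inspected
    if tree.final_cue not in case:
        raise DomainError(f"case is missing a value for cue {tree.final_cue!r}")
    inspected += 1
    value = case[tree.final_cue]
    return tree.final_labels.get(value, tree.final_default), inspected


@dataclass(frozen=True)
class ConfusionCounts:
    """Hits, misses, false alarms and correct rejections of a classifier."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    @property
    def n(self) -> int:
        return self.hits + self.misses + self.false_alarms + self.correct_rejections


@dataclass(frozen=True)
class FFTEvaluation:
    confusion: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    frugality: float  # mean cues inspected per case


def evaluate_fft(tree: FastFrugalTree, data: CaseDataset) -> FFTEvaluation:
    """Classify every record and tally the confusion counts and frugality."""
    pos = data.positive_outcome
    hits = misses = fa = cr = 0
    inspected_total = 0
    for _, row in data.df.iterrows():
        label, inspected = classify_case(tree, row)
        inspected_total += inspected
        actual_pos = row[OUTCOME] == pos
        assigned_pos = label == pos
        if actual_pos and assigned_pos:
            hits += 1
        elif actual_pos:
            misses += 1
        elif assigned_pos:
            fa += 1
        else:
            cr += 1
    n_pos, n_neg = hits + misses, fa + cr
    return FFTEvaluation(
        confusion=ConfusionCounts(hits, misses, fa, cr),
        sensitivity=hits / n_pos if n_pos else None,
        specificity=cr / n_neg if n_neg else None,
        frugality=inspected_total / data.n,
    )


# ---------------------------------------------------------------------------
# naive Bayes comparator

def naive_bayes_posterior(
    base_rate: float,
    cue_params: Mapping[str, tuple[float, float]],
    case: Mapping[str, bool],
) -> float:
    """Posterior under conditional independence from (sensitivity, FPR) pairs.

    ``cue_params[name] = (sensitivity, false_positive_rate)``; ``case``
    maps cue names to True (positive value observed) or False.  Equivalent
    to posterior odds = prior odds times the product of per-cue likelihood
    ratios; the 0.5 threshold makes it a classifier.
    """
    a = Fraction(base_rate)
    b = 1 - Fraction(base_rate)
    for name, observed_positive in case.items():
        if name not in cue_params:
            raise DomainError(f"no parameters for cue {name!r}")
        sens, fpr = (Fraction(x) for x in cue_params[name])
        a *= sens if observed_positive else 1 - sens
        b *= fpr if observed_positive else 1 - fpr
    if a + b == 0:
        raise UndefinedPosteriorError("evidence has probability 0 under both outcomes")
    return float(a / (a + b))


# ---------------------------------------------------------------------------
# exit-structure enumeration / ROC

#: combinatorial guard for exit-structure enumeration
MAX_ROC_LEVELS = 12


def fft_from_exit_structure(
    data: CaseDataset, cue_order: Sequence[str], sides: Sequence[str]
) -> FastFrugalTree:
    """Build an FFT from an explicit exit-side assignment.

    ``sides[i]`` is ``"positive"`` (exit on the positive value toward the
    positive outcome) or ``"negative"`` for each non-final level; the final
    level always carries both exits.  This is the override hook for
    reproducing published trees whose exit structure differs from the
    ZigZag rule's output.
    """
    if len(sides) != len(cue_order) - 1:
        raise DomainError("need one exit side per non-final level")
    pos_label = data.positive_outcome
    neg_label = data.negative_outcome()
    levels = []
    for cue, side in zip(cue_order, sides):
        if side not in ("positive", "negative"):
            raise DomainError(f"unknown exit side {side!r}")
        pos_val = data.positive_values[cue]
        neg_val = next(v for v in data.categories[cue] if v != pos_val)
        if side == "positive":
            levels.append(FFTLevel(cue=cue, exit_value=pos_val, exit_label=pos_label))
        else:
            levels.append(FFTLevel(cue=cue, exit_value=neg_val, exit_label=neg_label))
    final = cue_order[-1]
    pos_val = data.positive_values[final]
    neg_val = next(v for v in data.categories[final] if v != pos_val)
    return FastFrugalTree(
        levels=tuple(levels),
        final_cue=final,
        final_labels={pos_val: pos_label, neg_val: neg_label},
        final_default=neg_label,
        k=0,
    )


def exit_structure_roc(
    data: CaseDataset, cue_order: Sequence[str]
) -> list[tuple[float, float]]:
    """(false-alarm rate, hit rate) for every exit structure over the cue order.

    Enumerates all 2**(L-1) assignments of exit sides to non-final levels,
    evaluates each tree, and returns the distinct points sorted by FAR,
    always including the two degenerate classifiers (0, 0) and (1, 1).
    """
    L = len(cue_order)
    if L > MAX_ROC_LEVELS:
        raise DomainError(f"refusing to enumerate more than {MAX_ROC_LEVELS} levels")
    for cue in cue_order:
        if not data.is_binary(cue):
            raise DomainError(f"cue {cue!r} is not binary")
    points = {(0.0, 0.0), (1.0, 1.0)}
    for sides in itertools.product(("positive", "negative"), repeat=L - 1):
        tree = fft_from_exit_structure(data, cue_order, sides)
        ev = evaluate_fft(tree, data)
        c = ev.confusion
        n_pos, n_neg = c.hits + c.misses, c.false_alarms + c.correct_rejections
        far = c.false_alarms / n_neg if n_neg else 0.0
        hr = c.hits / n_pos if n_pos else 1.0
        points.add((far, hr))
    return sorted(points)
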