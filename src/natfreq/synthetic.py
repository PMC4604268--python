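"""Synthetic data: natural sampling, printed fixtures, and generated environments.

Natural sampling is the process by which natural frequencies arise in the
first place: individuals are encountered one at a time, each carrying a
true hypothesis and the cue values it generated.  :func:`sample_cases`
simulates exactly that — hypothesis from the priors, then each cue value
from its context-resolved likelihood — and :func:`estimate_task` closes
the loop by recovering the task parameters as empirical proportions.

:func:`green_mehr_fixture` reconstructs the 89-patient chest-pain cohort
behind the classic heart-disease fast-and-frugal tree from its published
aggregate counts, and :func:`merged_cue_environment` generates
pair-comparison environments in which two individually weak cues merge
into a perfectly valid one.

Every stochastic operation takes an explicit integer seed (default 0);
the same seed always yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .fft import OUTCOME, CaseDataset, FastFrugalTree, FFTLevel
from .cues import CRITERION, PairComparisonEnvironment
from .task import EMPTY_CONTEXT, Cue, DiagnosticTask, HypothesisSpace


@dataclass(frozen=True)
class GeneratorConfig:
    """Reproducible generator settings: same config, identical output."""

    seed: int = 0
    n: int = 500
    task: DiagnosticTask | None = None
    target_validities: Mapping[str, float] | None = None


def sample_cases(
    task: DiagnosticTask,
    n: int,
    seed: int = 0,
    positive_values: Mapping[str, str] | None = None,
) -> CaseDataset:
    """Draw n independent cases from a task by natural sampling.

    Each record draws its hypothesis from the priors, then each cue value
    in cue order from the context-resolved likelihoods; the outcome column
    is the hypothesis label.  The first hypothesis label plays the positive
    outcome; ``positive_values`` defaults to each cue's first category.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    labels = task.hypothesis_space.labels
    priors = np.array([float(task.hypothesis_space.priors[h]) for h in labels])
    priors = priors / priors.sum()
    hyp_idx = rng.choice(len(labels), size=n, p=priors)
    df = pd.DataFrame({OUTCOME: [labels[i] for i in hyp_idx]})
    for i, cue in enumerate(task.cues):
        values = np.empty(n, dtype=object)
        ctx_cols = [c.name for c in task.cues[:i]]
        group_cols = [OUTCOME] + ctx_cols
        for key, idx in df.groupby(group_cols, sort=True).groups.items():
            key = key if isinstance(key, tuple) else (key,)
            hypothesis = key[0]
            assignment = dict(zip(ctx_cols, key[1:]))
            dist = cue.distribution(hypothesis, assignment)
            probs = np.array([float(dist[c]) for c in cue.categories])
            probs = probs / probs.sum()
            values[df.index.get_indexer(idx)] = rng.choice(
                cue.categories, size=len(idx), p=probs
            )
        df[cue.name] = values
    df = df[[c.name for c in task.cues] + [OUTCOME]]
    return CaseDataset(
        df=df,
        cue_names=task.cue_names,
        categories={c.name: c.categories for c in task.cues},
        positive_values=dict(positive_values or {c.name: c.categories[0] for c in task.cues}),
        positive_outcome=labels[0],
    )


def estimate_task(data: CaseDataset, use_contexts: bool = False) -> DiagnosticTask:
    """Recover a task from case data: priors and likelihoods as proportions.

    With ``use_contexts=False`` (the default) every cue is estimated with
    the empty context, i.e. assuming conditional independence given the
    outcome.  With contexts, one distribution is estimated per combination
    of earlier cue values; cells with no records are omitted (their
    likelihoods are undefined — ``validate_task`` will flag them).
    All proportions are exact Fractions of the observed counts.
    """
    labels = data.outcome_labels
    n = data.n
    priors = {
        h: Fraction(int((data.df[OUTCOME] == h).sum()), n) for h in labels
    }
    cues = []
    for i, name in enumerate(data.cue_names):
        cats = data.categories[name]
        likelihoods: dict[tuple[str, frozenset], dict[str, Fraction]] = {}
        if not use_contexts:
            for h in labels:
                sub = data.df[data.df[OUTCOME] == h]
                if len(sub) == 0:
                    continue
                counts = sub[name].value_counts()
                likelihoods[(h, EMPTY_CONTEXT)] = {
                    c: Fraction(int(counts.get(c, 0)), len(sub)) for c in cats
                }
        else:
            earlier = list(data.cue_names[:i])
            group_cols = [OUTCOME] + earlier
            for key, sub in data.df.groupby(group_cols, sort=True):
                key = key if isinstance(key, tuple) else (key,)
                ctx = frozenset(zip(earlier, key[1:]))
                counts = sub[name].value_counts()
                likelihoods[(key[0], ctx)] = {
                    c: Fraction(int(counts.get(c, 0)), len(sub)) for c in cats
                }
        cues.append(Cue(name=name, categories=cats, likelihoods=likelihoods))
    return DiagnosticTask(
        hypothesis_space=HypothesisSpace(labels=labels, priors=priors),
        cues=tuple(cues),
        reference_population=n,
    )


# ---------------------------------------------------------------------------
# Green & Mehr chest-pain cohort

HIGH_RISK = "heart attack"
LOW_RISK = "no heart attack"

# (ST, CP, OS, outcome, count) — aggregate-faithful synthetic reconstruction.
# Printed constraints: 89 patients; 33 ST+; of the 56 ST-: 29 CP-; of the 27
# ST-CP+: 17 OS+ and 10 OS-; 15 positives total, all routed to high-risk
# exits (10 placed at the ST+ exit, 5 at the OS+ exit); 0 positives among
# low-risk-routed patients.  The within-group splits below (CP/OS values of
# the ST+ group, OS values of the ST-CP- group) are not printed anywhere and
# are fixed arbitrarily.
_GREEN_MEHR_ROWS = [
    ("+", "+", "+", HIGH_RISK, 10),
    ("+", "+", "+", LOW_RISK, 2),
    ("+", "+", "-", LOW_RISK, 8),
    ("+", "-", "+", LOW_RISK, 7),
    ("+", "-", "-", LOW_RISK, 6),
    ("-", "-", "+", LOW_RISK, 14),
    ("-", "-", "-", LOW_RISK, 15),
    ("-", "+", "+", HIGH_RISK, 5),
    ("-", "+", "+", LOW_RISK, 12),
    ("-", "+", "-", LOW_RISK, 10),
]


def green_mehr_fixture() -> CaseDataset:
    """Synthetic 89-patient chest-pain cohort matching the published aggregates.

    The cohort emulates the emergency-medicine dataset of Green & Mehr
    (J. Fam. Pract. 45, 1997) as described by its published summary counts.
    Cues: ST (elevated ST segment), CP (chest pain the chief symptom), OS
    (at least one other symptom), values "+"/"-"; outcome is heart attack
    vs. no heart attack.  Routing counts (33 ST+; 29 of ST- are CP-; 17
    OS+ and 10 OS- among ST-CP+), classification counts (50 high / 39 low)
    and confusion counts (15 hits, 35 false alarms, 0 misses, 39 correct
    rejections) under the published tree all match; the record-level
    detail beyond those aggregates is synthetic.
    """
    rows = []
    for st, cp, os_, outcome, count in _GREEN_MEHR_ROWS:
        rows.extend([(st, cp, os_, outcome)] * count)
    df = pd.DataFrame(rows, columns=["ST", "CP", "OS", OUTCOME])
    return CaseDataset(
        df=df,
        cue_names=("ST", "CP", "OS"),
        categories={c: ("+", "-") for c in ("ST", "CP", "OS")},
        positive_values={c: "+" for c in ("ST", "CP", "OS")},
        positive_outcome=HIGH_RISK,
    )


def green_mehr_tree() -> FastFrugalTree:
    """The published chest-pain fast-and-frugal tree.

    ST+ exits to high risk; then CP- exits to low risk; the final OS level
    sends OS+ to high risk and OS- to low risk.
    """
    return FastFrugalTree(
        levels=(
            FFTLevel(cue="ST", exit_value="+", exit_label=HIGH_RISK),
            FFTLevel(cue="CP", exit_value="-", exit_label=LOW_RISK),
        ),
        final_cue="OS",
        final_labels={"+": HIGH_RISK, "-": LOW_RISK},
        final_default=LOW_RISK,
        k=1,
    )


# ---------------------------------------------------------------------------
# merged-cue pair-comparison environments

#: criterion bonus for merged-cue-positive objects; any bonus > 1 guarantees
#: that the merged cue, where it discriminates, always points correctly
_BONUS = 10.0

#: flip fraction for C1 against the criterion ranking (validity -> 1 - flip)
_C1_FLIP = 0.2

# joint cell probabilities for (C2, C3), keyed (c2, c3), chosen in closed form
# so that each single cue's validity lands at 0.60 while the merged cue is
# perfectly valid by construction (derivations in docs/methods.md)
_XOR_P11 = (3.4 - math.sqrt(10.0)) / 2
_JOINT_C2C3 = {
    "AND": {(1, 1): 0.1, (1, 0): 0.4, (0, 1): 0.4, (0, 0): 0.1},
    "OR": {(1, 1): 0.1, (1, 0): 0.4, (0, 1): 0.4, (0, 0): 0.1},
    "XOR": {(1, 1): _XOR_P11, (1, 0): 0.3, (0, 1): 0.3, (0, 0): 0.4 - _XOR_P11},
}

_BOOL = {
    "AND": lambda a, b: a & b,
    "OR": lambda a, b: a | b,
    "XOR": lambda a, b: a ^ b,
}


def _quota_counts(n: int, probs: Sequence[float]) -> list[int]:
    """Integer counts for n objects by largest remainder (sums to n)."""
    quotas = [n * p for p in probs]
    counts = [int(q) for q in quotas]
    remainders = sorted(
        range(len(probs)), key=lambda i: (quotas[i] - counts[i], -i), reverse=True
    )
    for i in remainders[: n - sum(counts)]:
        counts[i] += 1
    return counts


def _interleave(labels_with_counts: list[tuple[object, int]]) -> list[object]:
    """Spread each label evenly along positions (quota round-robin)."""
    total = sum(c for _, c in labels_with_counts)
    assigned = [0] * len(labels_with_counts)
    out = []
    for pos in range(total):
        best, best_lag = None, None
        for i, (_, count) in enumerate(labels_with_counts):
            if assigned[i] >= count:
                continue
            lag = count * (pos + 1) / total - assigned[i]
            if best is None or lag > best_lag:
                best, best_lag = i, lag
        assigned[best] += 1
        out.append(labels_with_counts[best][0])
    return out


def merged_cue_environment(op: str, n: int = 500, seed: int = 0) -> PairComparisonEnvironment:
    """Three-cue environment in which op(C2, C3) is a perfectly valid cue.

    The criterion is a large bonus for objects whose merged cue is present
    plus a Uniform(0, 1) jitter, so whenever the merged cue discriminates a
    pair it points to the higher criterion — merged validity is exactly 1
    for every seed, by construction.  C1 is the above-median criterion
    indicator with a fixed 20% of each half flipped (validity 0.80); the
    (C2, C3) cell counts follow an engineered joint distribution giving
    each component cue a validity of 0.60.  Cell labels and flips are
    spread evenly along the criterion ranking, so the realized validities
    sit at their targets up to O(1/n) rather than sampling noise — these
    are engineered environments with fixed cue structure, not an i.i.d.
    sample.  The seed only jitters the criterion values.
    """
    if op not in _JOINT_C2C3:
        raise DomainError(f"unknown Boolean op {op!r}; expected AND, OR or XOR")
    if n < 20:
        raise DomainError("n must be >= 20")
    rng = np.random.default_rng(seed)
    cells = list(_JOINT_C2C3[op].items())
    counts = _quota_counts(n, [p for _, p in cells])
    # split cells by merged-cue value; within each group, interleave the
    # cells along the criterion ranking so cross-cell pairs sit at 50%
    groups: dict[bool, list[tuple[tuple[int, int], int]]] = {True: [], False: []}
    for (cell, _), count in zip(cells, counts):
        m = bool(_BOOL[op](bool(cell[0]), bool(cell[1])))
        if count:
            groups[m].append((cell, count))
    rows = []  # (criterion, c2, c3)
    for m, members in groups.items():
        size = sum(c for _, c in members)
        if not size:
            continue
        jitter = np.sort(rng.uniform(0.0, 1.0, size=size))
        order = _interleave(members)
        for u, (c2v, c3v) in zip(jitter, order):
            rows.append(((_BONUS if m else 0.0) + u, c2v, c3v))
    rows.sort()  # ascending criterion
    criterion = np.array([r[0] for r in rows])
    c2 = np.array([r[1] for r in rows])
    c3 = np.array([r[2] for r in rows])
    # C1: above-median indicator with an interleaved 20% of each half flipped
    half = n // 2
    c1 = np.zeros(n, dtype=int)
    for lo, hi, base in ((0, half, 0), (half, n, 1)):
        size = hi - lo
        n_flip = _quota_counts(size, [_C1_FLIP, 1 - _C1_FLIP])[0]
        pattern = _interleave([(1 - base, n_flip), (base, size - n_flip)])
        c1[lo:hi] = pattern
    df = pd.DataFrame({"C1": c1, "C2": c2, "C3": c3, CRITERION: criterion})
    return PairComparisonEnvironment(df=df, cue_names=("C1", "C2", "C3"))


# ---------------------------------------------------------------------------
# random task generation (for property suites and demos)

def random_task(
    seed: int = 0,
    n_hypotheses: int | None = None,
    n_cues: int | None = None,
    max_categories: int = 3,
    balanced: bool = False,
) -> DiagnosticTask:
    """A random valid task with conditionally independent cues.

    Priors and likelihood rows are Dirichlet(1, ..., 1) draws, so every
    branch has positive probability.  With ``balanced=True`` the task has
    two hypotheses with priors drawn uniformly from [0.4, 0.6] — the
    design for parameter-recovery checks, where precision is limited by
    the smallest per-hypothesis stratum rather than by the estimator.
    Used by the property suites (format equivalence, sequential updating,
    parameter recovery) and for demos.
    """
    rng = np.random.default_rng(seed)
    n_h = 2 if balanced else int(n_hypotheses or rng.integers(2, 4))
    n_c = int(n_cues or rng.integers(1, 4))
    labels = tuple(f"H{i + 1}" for i in range(n_h))
    if balanced:
        p0 = float(rng.uniform(0.4, 0.6))
        priors_arr = np.array([p0, 1.0 - p0])
    else:
        priors_arr = rng.dirichlet(np.ones(n_h))
    priors = {h: float(p) for h, p in zip(labels, priors_arr)}
    cues = []
    for j in range(n_c):
        arity = int(rng.integers(2, max_categories + 1))
        cats = tuple(f"v{i + 1}" for i in range(arity))
        likelihoods = {}
        for h in labels:
            row = rng.dirichlet(np.ones(arity))
            likelihoods[(h, EMPTY_CONTEXT)] = {c: float(p) for c, p in zip(cats, row)}
        cues.append(Cue(name=f"cue{j + 1}", categories=cats, likelihoods=likelihoods))
    return DiagnosticTask(
        hypothesis_space=HypothesisSpace(labels=labels, priors=priors), cues=tuple(cues)
    )
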