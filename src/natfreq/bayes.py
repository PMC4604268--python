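"""Posterior computation in probability and frequency formats.

Two routes to the same posterior p(H | evidence):

* the probability route — prior times likelihoods, normalised over
  hypotheses (the textbook updating rule); computed internally in exact
  rational arithmetic so the equivalence with the frequency route is exact,
  not merely approximate;
* the frequency route — read joint counts off a natural frequency tree and
  form the Laplacian proportion f(evidence & H) / f(evidence).

Conversion between the two formats is :func:`to_frequency_tree` (probability
task -> counted tree, with a configurable rounding policy) and
:func:`tree_to_task` (counted tree -> probability task, likelihoods as exact
count ratios).  :func:`score_response` classifies a numeric answer against
the exact posterior the way Bayesian-reasoning studies score participants:
correct if exact or if rounded to the nearest whole percentage point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

from .errors import DomainError, UndefinedPosteriorError
from .task import (
    EMPTY_CONTEXT,
    HYPOTHESIS_LAYER,
    Cue,
    DiagnosticTask,
    HypothesisSpace,
    NaturalFrequencyTree,
    Number,
    TreeLayer,
    joint_fraction,
)


class DegenerateCountWarning(UserWarning):
    """A rounded tree count collapsed to 0 although its exact value is > 0."""


@dataclass(frozen=True)
class RoundingPolicy:
    """How expected counts are turned into the integers printed in a tree.

    mode
        ``"nearest"`` — round half to even; ``"floor"`` — truncate;
        ``"exact"`` — keep exact rationals (no rounding at all).
    conservation
        After rounding, adjust children by largest remainder so they sum
        exactly to their parent's count.
    """

    mode: str = "nearest"
    conservation: bool = True

    def __post_init__(self):
        if self.mode not in ("nearest", "floor", "exact"):
            raise DomainError(f"unknown rounding mode {self.mode!r}")


NEAREST = RoundingPolicy("nearest", conservation=True)
FLOOR = RoundingPolicy("floor", conservation=True)
EXACT = RoundingPolicy("exact", conservation=False)


def _allocate(parent: Number, probs: list[Fraction], policy: RoundingPolicy) -> list[Number]:
    """Split a parent count among children with the policy's rounding."""
    quotas = [Fraction(parent) * p for p in probs]
    if policy.mode == "exact":
        return quotas
    if policy.mode == "nearest":
        rounded = [round(q) for q in quotas]  # Fraction.round: half to even
    else:
        rounded = [int(q) if q >= 0 else -int(-q) for q in quotas]  # floor for q >= 0
    if policy.conservation:
        diff = int(round(Fraction(parent))) - sum(rounded) if policy.mode == "nearest" else int(parent) - sum(rounded)
        # distribute the deficit/surplus by largest remainder in the needed
        # direction; ties broken by declared branch order
        while diff != 0:
            step = 1 if diff > 0 else -1
            if step > 0:
                key = lambda i: (quotas[i] - rounded[i], -i)
            else:
                key = lambda i: (rounded[i] - quotas[i], -i)
            candidates = [i for i in range(len(probs)) if rounded[i] + step >= 0]
            i = max(candidates, key=key)
            rounded[i] += step
            diff -= step
    return rounded


def to_frequency_tree(
    task: DiagnosticTask, N: int, policy: RoundingPolicy = NEAREST
) -> NaturalFrequencyTree:
    """Convert a probability-format task into a hypothesis-first frequency tree.

    Layer 1 partitions the N individuals by the priors; each further layer
    partitions every node by the cue's context-resolved likelihoods, rounding
    per ``policy``.  With the exact policy, counts are exact rationals and
    the tree reproduces the task's probabilities with no loss.

    Emits a :class:`DegenerateCountWarning` when a rounded count is 0 while
    its exact expectation is positive (N too small for the rarest branch).
    """
    if N < 1:
        raise DomainError("N must be >= 1")
    hs = task.hypothesis_space
    layers = [TreeLayer(on=HYPOTHESIS_LAYER, categories=hs.labels)]
    for cue in task.cues:
        layers.append(TreeLayer(on=cue.name, categories=cue.categories))

    nodes: dict[tuple[str, ...], Number] = {(): N}
    frontier = [()]
    # layer 1: hypotheses
    prior_probs = [Fraction(hs.priors[h]) for h in hs.labels]
    counts = _allocate(N, prior_probs, policy)
    for h, c, q in zip(hs.labels, counts, prior_probs):
        nodes[(h,)] = c
        if c == 0 and q > 0:
            warnings.warn(
                f"count for hypothesis {h!r} rounds to 0 (exact {float(q * N):g})",
                DegenerateCountWarning,
                stacklevel=2,
            )
    frontier = [(h,) for h in hs.labels]
    # cue layers
    for depth, cue in enumerate(task.cues):
        new_frontier = []
        for path in frontier:
            hypothesis = path[0]
            assignment = dict(zip(task.cue_names[:depth], path[1:]))
            dist = cue.distribution(hypothesis, assignment)
            probs = [Fraction(dist[cat]) for cat in cue.categories]
            counts = _allocate(nodes[path], probs, policy)
            for cat, c, q in zip(cue.categories, counts, probs):
                nodes[path + (cat,)] = c
                if c == 0 and q > 0 and nodes[path] > 0:
                    warnings.warn(
                        f"count at {path + (cat,)!r} rounds to 0 "
                        f"(exact {float(q * nodes[path]):g})",
                        DegenerateCountWarning,
                        stacklevel=2,
                    )
                new_frontier.append(path + (cat,))
        frontier = new_frontier
    return NaturalFrequencyTree(
        orientation="hypothesis-first", root_count=N, layers=tuple(layers), nodes=nodes
    )


def tree_to_task(tree: NaturalFrequencyTree) -> DiagnosticTask:
    """Recover a probability-format task from a hypothesis-first tree.

    Priors and likelihoods are exact count ratios (Fractions), so
    ``to_frequency_tree(tree_to_task(t), N, EXACT)`` reproduces the source
    counts exactly.  Cues are emitted with full contexts (one distribution
    per path), which is lossless for dependent and independent cues alike.
    """
    if tree.orientation != "hypothesis-first":
        raise DomainError("tree_to_task requires a hypothesis-first tree")
    if tree.layers[0].on != HYPOTHESIS_LAYER:
        raise DomainError("first layer must partition on the hypothesis")
    N = tree.root_count
    labels = tree.layers[0].categories
    priors = {h: Fraction(tree.nodes[(h,)]) / Fraction(N) for h in labels}
    cues = []
    cue_layers = tree.layers[1:]
    for depth, layer in enumerate(cue_layers):
        likelihoods: dict[tuple[str, frozenset], dict[str, Fraction]] = {}
        for path in tree.paths():
            if len(path) != depth + 1:
                continue
            parent_count = tree.nodes[path]
            children_present = [c for c in layer.categories if path + (c,) in tree.nodes]
            if not children_present:
                continue
            if parent_count == 0:
                raise UndefinedPosteriorError(
                    f"cannot recover likelihoods below zero-count node {path!r}"
                )
            hypothesis = path[0]
            ctx = frozenset(zip([l.on for l in cue_layers[:depth]], path[1:]))
            likelihoods[(hypothesis, ctx)] = {
                c: Fraction(tree.nodes[path + (c,)]) / Fraction(parent_count)
                for c in layer.categories
            }
        cues.append(Cue(name=layer.on, categories=layer.categories, likelihoods=likelihoods))
    return DiagnosticTask(
        hypothesis_space=HypothesisSpace(labels=labels, priors=priors),
        cues=tuple(cues),
        reference_population=int(N) if N == int(N) else None,
    )


@dataclass(frozen=True)
class PosteriorResult:
    """A posterior distribution over hypotheses given observed evidence.

    ``exact`` holds the rational-arithmetic distribution from which the
    float ``distribution`` is derived.  When the posterior was read off a
    frequency tree, ``joint_counts`` and ``evidence_count`` carry the raw
    natural frequencies and :meth:`as_fraction` reports the Laplacian
    proportion for a focal hypothesis (default: the first label).
    """

    distribution: Mapping[str, float]
    evidence: Mapping[str, str]
    exact: Mapping[str, Fraction]
    joint_counts: Mapping[str, Number] | None = None
    evidence_count: Number | None = None
    focal: str | None = None

    def as_fraction(self, hypothesis: str | None = None) -> tuple[Number, Number] | None:
        if self.joint_counts is None:
            return None
        h = hypothesis or self.focal or next(iter(self.distribution))
        return (self.joint_counts[h], self.evidence_count)


def _normalize(exact: dict[str, Fraction], evidence) -> dict[str, Fraction]:
    total = sum(exact.values())
    if total == 0:
        raise UndefinedPosteriorError(
            f"evidence {dict(evidence)!r} has probability 0; posterior undefined"
        )
    return {h: p / total for h, p in exact.items()}


def posterior(task: DiagnosticTask, evidence: Mapping[str, str]) -> PosteriorResult:
    """Posterior distribution given a cue-value assignment (any number of cues).

    ``distribution[h] = p(h) * prod(likelihoods) / sum over hypotheses``,
    computed with context-resolved likelihoods, so it is valid for dependent
    cue chains as well as conditionally independent ones.
    """
    joint = {h: joint_fraction(task, h, evidence) for h in task.hypothesis_space.labels}
    exact = _normalize(joint, evidence)
    return PosteriorResult(
        distribution={h: float(p) for h, p in exact.items()},
        evidence=dict(evidence),
        exact=exact,
        focal=task.hypothesis_space.labels[0],
    )


def sequential_posterior(task: DiagnosticTask, evidence: Mapping[str, str]) -> PosteriorResult:
    """Chained single-cue updating: each posterior becomes the next prior.

    For conditionally independent cues this equals the one-shot
    :func:`posterior`.  Cues with declared contexts are resolved against the
    evidence accumulated so far, so the chain remains exact for dependent
    cues provided the evidence covers their context cues.
    """
    current = {h: Fraction(task.hypothesis_space.priors[h]) for h in task.hypothesis_space.labels}
    seen: dict[str, str] = {}
    for cue in task.cues:
        if cue.name not in evidence:
            continue
        value = evidence[cue.name]
        if value not in cue.categories:
            raise DomainError(f"cue {cue.name!r}: unknown category {value!r}")
        step = {}
        for h in current:
            dist = cue.distribution(h, seen)
            step[h] = current[h] * Fraction(dist[value])
        current = _normalize(step, evidence)
        seen[cue.name] = value
    if not seen:
        current = _normalize(current, evidence)
    return PosteriorResult(
        distribution={h: float(p) for h, p in current.items()},
        evidence=dict(evidence),
        exact=current,
        focal=task.hypothesis_space.labels[0],
    )


def posterior_from_tree(
    tree: NaturalFrequencyTree, evidence: Mapping[str, str], focal: str | None = None
) -> PosteriorResult:
    """Posterior as a ratio of natural frequencies read off the tree.

    ``distribution[h] = f(evidence & h) / f(evidence)``; the raw counts are
    kept so the result can be displayed as, e.g., ``8/103``.
    """
    if tree.orientation == "hypothesis-first":
        labels = tree.layers[0].categories
        cue_layer_names = [l.on for l in tree.layers[1:]]
        for name in evidence:
            if name not in cue_layer_names:
                raise DomainError(f"evidence cue {name!r} is not a tree layer")
        depth = 0
        for name in cue_layer_names:
            if name in evidence:
                depth += 1
            else:
                break
        if depth != len(evidence):
            raise DomainError("evidence must cover a prefix of the tree's cue layers")
        path_values = tuple(evidence[name] for name in cue_layer_names[:depth])
        joint = {h: tree.count((h,) + path_values) for h in labels}
    elif tree.orientation == "cue-first":
        cue_layer_names = [l.on for l in tree.layers[:-1]]
        labels = tree.layers[-1].categories
        if set(evidence) != set(cue_layer_names):
            raise DomainError("cue-first trees require evidence for every cue layer")
        path_values = tuple(evidence[name] for name in cue_layer_names)
        joint = {h: tree.count(path_values + (h,)) for h in labels}
    else:
        raise DomainError(f"unknown orientation {tree.orientation!r}")
    total = sum(joint.values())
    if total == 0:
        raise UndefinedPosteriorError(
            f"f({dict(evidence)!r}) = 0 in the tree; posterior undefined"
        )
    exact = {h: Fraction(joint[h]) / Fraction(total) for h in labels}
    return PosteriorResult(
        distribution={h: float(p) for h, p in exact.items()},
        evidence=dict(evidence),
        exact=exact,
        joint_counts=joint,
        evidence_count=total,
        focal=focal or labels[0],
    )


# ---------------------------------------------------------------------------
# response scoring

#: tolerance, in percentage points, for counting an answer as the exact solution
EXACT_TOLERANCE_PP = 0.05


@dataclass(frozen=True)
class ResponseScore:
    """Classification of a numeric answer against the exact posterior."""

    verdict: str  # "exact" | "rounded" | "incorrect"
    exact_value: float  # the true posterior, as a proportion
    response: float  # the answer as given


def score_response(
    response: float, exact_value: float, input_scale: str = "percent"
) -> ResponseScore:
    """Score an answer: exact, rounded to the nearest whole percent, or incorrect.

    ``exact_value`` is the true posterior as a proportion in [0, 1];
    ``response`` is on the declared scale (percent in [0, 100] or proportion
    in [0, 1]).  "Exact" tolerates 0.05 percentage points; "rounded" accepts
    the exact percent rounded to the nearest whole point (half away from
    zero, so 7.5 -> 8).
    """
    if input_scale not in ("percent", "proportion"):
        raise DomainError(f"unknown input scale {input_scale!r}")
    if input_scale == "percent":
        if not (0 <= response <= 100):
            raise DomainError(f"percent response {response!r} outside [0, 100]")
        resp_pp = float(response)
    else:
        if not (0 <= response <= 1):
            raise DomainError(f"proportion response {response!r} outside [0, 1]")
        resp_pp = float(response) * 100
    exact_pp = float(exact_value) * 100
    if abs(resp_pp - exact_pp) <= EXACT_TOLERANCE_PP:
        verdict = "exact"
    elif resp_pp == int(exact_pp + 0.5) and resp_pp == int(resp_pp):
        verdict = "rounded"
    else:
        verdict = "incorrect"
    return ResponseScore(verdict=verdict, exact_value=float(exact_value), response=float(response))
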