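"""Diagnostic-task and natural-frequency-tree domain types with JSON/DOT I/O.

A diagnostic task is the probability-format description of an inference
problem: a set of mutually exclusive hypotheses with prior probabilities
(e.g. *cancer* / *no cancer* with prevalence 1%), and an ordered list of
categorical cues (diagnostic tests), each with a likelihood distribution
over its categories conditional on the hypothesis — and, optionally, on
the values of earlier cues (a *context*), when cues are not conditionally
independent.

A natural frequency tree is the frequency-format description of the same
problem: a reference population of N individuals decomposed layer by layer
into integer counts, first by hypothesis and then by cue value (or the
other way round for outcome-at-the-leaves trees used for classification).

All probabilities are stored as proportions in [0, 1]; percent notation is
purely a display concern.  Probability values may be floats or
:class:`fractions.Fraction`; exact-rational values survive serialization
round trips through their string form.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence, Union

from .errors import DomainError, MalformedInputError, TaskValidationError

Number = Union[int, float, Fraction]

#: sum-to-one tolerance for probability distributions
PROB_TOL = 1e-9

#: a context: frozenset of (cue name, value) pairs; empty = conditionally independent
Context = frozenset

EMPTY_CONTEXT: Context = frozenset()


def _as_number(x) -> Number:
    """Parse a JSON probability value; strings like '19/20' become Fractions."""
    if isinstance(x, str):
        try:
            return Fraction(x)
        except (ValueError, ZeroDivisionError) as exc:
            raise MalformedInputError(f"not a number: {x!r}") from exc
    if isinstance(x, bool) or not isinstance(x, (int, float, Fraction)):
        raise MalformedInputError(f"not a number: {x!r}")
    return x


def _num_to_json(x: Number):
    if isinstance(x, Fraction):
        return str(x)
    return x


@dataclass(frozen=True)
class HypothesisSpace:
    """Mutually exclusive, exhaustive hypotheses with prior probabilities."""

    labels: tuple[str, ...]
    priors: Mapping[str, Number]

    def violations(self) -> list[str]:
        out = []
        if len(self.labels) < 2:
            out.append("hypotheses: fewer than 2 labels")
        if len(set(self.labels)) != len(self.labels):
            out.append("hypotheses: labels not unique")
        if set(self.priors) != set(self.labels):
            out.append("hypotheses: priors do not match labels")
            return out
        total = sum(self.priors[h] for h in self.labels)
        if abs(total - 1) > PROB_TOL:
            out.append(f"hypotheses: priors sum to {float(total)!r}, not 1")
        for h in self.labels:
            if not (0 <= self.priors[h] <= 1):
                out.append(f"hypotheses: prior of {h!r} outside [0, 1]")
        return out


@dataclass(frozen=True)
class Cue:
    """A categorical cue (diagnostic test) with conditional likelihoods.

    ``likelihoods`` maps ``(hypothesis label, context)`` to a distribution
    over ``categories``.  A cue declared only with the empty context is
    conditionally independent of earlier cues given the hypothesis;
    contexts, when used, must assign values to *all* earlier cues.
    """

    name: str
    categories: tuple[str, ...]
    likelihoods: Mapping[tuple[str, Context], Mapping[str, Number]]

    def distribution(self, hypothesis: str, assignment: Mapping[str, str]) -> Mapping[str, Number]:
        """Resolve the likelihood distribution for a hypothesis given earlier cue values."""
        key = (hypothesis, EMPTY_CONTEXT)
        if key in self.likelihoods:
            return self.likelihoods[key]
        for (h, ctx), dist in self.likelihoods.items():
            if h != hypothesis:
                continue
            if all(assignment.get(c) == v for c, v in ctx):
                return dist
        raise DomainError(
            f"cue {self.name!r}: no likelihood distribution for hypothesis "
            f"{hypothesis!r} in context {dict(assignment)!r}"
        )

    def context_cues(self) -> set[str]:
        return {c for (_, ctx) in self.likelihoods for (c, _) in ctx}


@dataclass(frozen=True)
class DiagnosticTask:
    """A Bayesian inference task: hypotheses, ordered cues, optional population N.

    Cue order is significant: contexts may refer only to earlier cues, and
    frequency-tree layers follow this order.
    """

    hypothesis_space: HypothesisSpace
    cues: tuple[Cue, ...]
    reference_population: int | None = None

    @property
    def cue_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.cues)

    def cue(self, name: str) -> Cue:
        for c in self.cues:
            if c.name == name:
                return c
        raise DomainError(f"unknown cue {name!r}")


def validate_task(task: DiagnosticTask) -> list[str]:
    """Return a list of invariant violations (empty iff the task is valid)."""
    out = list(task.hypothesis_space.violations())
    names = task.cue_names
    if len(set(names)) != len(names):
        out.append("cues: names not unique")
    labels = set(task.hypothesis_space.labels)
    for i, cue in enumerate(task.cues):
        prefix = f"cue {cue.name!r}"
        earlier = names[:i]
        if len(cue.categories) < 2:
            out.append(f"{prefix}: fewer than 2 categories")
        if len(set(cue.categories)) != len(cue.categories):
            out.append(f"{prefix}: duplicate categories")
        bad_ctx_refs = cue.context_cues() - set(earlier)
        if bad_ctx_refs:
            out.append(f"{prefix}: context refers to non-earlier cues {sorted(bad_ctx_refs)}")
        for (h, ctx), dist in cue.likelihoods.items():
            where = f"{prefix}, hypothesis {h!r}" + (f", context {dict(ctx)!r}" if ctx else "")
            if h not in labels:
                out.append(f"{where}: unknown hypothesis")
            if set(dist) != set(cue.categories):
                out.append(f"{where}: distribution categories do not match cue categories")
                continue
            total = sum(dist.values())
            if abs(total - 1) > PROB_TOL:
                out.append(f"{where}: distribution sums to {float(total)!r}, not 1")
            for cat, p in dist.items():
                if not (0 <= p <= 1):
                    out.append(f"{where}: p({cat!r}) outside [0, 1]")
        # context coverage: for each hypothesis, either the empty context or
        # every combination of earlier cue values must be present
        if not bad_ctx_refs:
            earlier_cats = [task.cues[j].categories for j in range(i)]
            for h in task.hypothesis_space.labels:
                keys = [ctx for (hh, ctx) in cue.likelihoods if hh == h]
                if not keys:
                    out.append(f"{prefix}: no likelihoods for hypothesis {h!r}")
                    continue
                if EMPTY_CONTEXT in keys:
                    continue
                have = set(keys)
                for combo in itertools.product(*earlier_cats):
                    ctx = frozenset(zip(earlier, combo))
                    if ctx not in have:
                        out.append(
                            f"{prefix}, hypothesis {h!r}: missing context "
                            f"{dict(zip(earlier, combo))!r}"
                        )
    if task.reference_population is not None and task.reference_population < 1:
        out.append("population: must be a positive integer")
    return out


def joint_probability(task: DiagnosticTask, hypothesis: str, assignment: Mapping[str, str]) -> float:
    """p(hypothesis & assignment): prior times the product of likelihoods.

    The assignment covers a prefix of the cue order (or any subset whose
    contexts are resolvable from the assigned values).
    """
    return float(joint_fraction(task, hypothesis, assignment))


def joint_fraction(task: DiagnosticTask, hypothesis: str, assignment: Mapping[str, str]) -> Fraction:
    """Exact-rational joint probability (floats converted via Fraction(float))."""
    if hypothesis not in task.hypothesis_space.labels:
        raise DomainError(f"unknown hypothesis {hypothesis!r}")
    known = set(task.cue_names)
    for name in assignment:
        if name not in known:
            raise DomainError(f"unknown cue {name!r}")
    p = Fraction(task.hypothesis_space.priors[hypothesis])
    seen: dict[str, str] = {}
    for cue in task.cues:
        if cue.name not in assignment:
            continue
        value = assignment[cue.name]
        if value not in cue.categories:
            raise DomainError(f"cue {cue.name!r}: unknown category {value!r}")
        dist = cue.distribution(hypothesis, seen)
        p *= Fraction(dist[value])
        seen[cue.name] = value
    return p


# ---------------------------------------------------------------------------
# task-spec JSON

def load_task(text: str) -> DiagnosticTask:
    """Parse and validate a task-spec JSON document.

    Raises :class:`MalformedInputError` naming the offending field on parse
    problems and :class:`TaskValidationError` carrying the violation list
    when the parsed task breaks an invariant.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise MalformedInputError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise MalformedInputError("top level: expected an object")
    try:
        hyps = doc["hypotheses"]
        labels = tuple(h["label"] for h in hyps)
        priors = {h["label"]: _as_number(h["prior"]) for h in hyps}
    except (KeyError, TypeError) as exc:
        raise MalformedInputError(f"hypotheses: missing or malformed field ({exc})") from exc
    cues = []
    for entry in doc.get("cues", []):
        try:
            name = entry["name"]
            categories = tuple(entry["categories"])
            likelihoods = {}
            for row in entry["likelihoods"]:
                ctx = frozenset((row.get("context") or {}).items())
                dist = {cat: _as_number(p) for cat, p in row["distribution"].items()}
                likelihoods[(row["hypothesis"], ctx)] = dist
        except (KeyError, TypeError) as exc:
            raise MalformedInputError(f"cues: missing or malformed field ({exc})") from exc
        cues.append(Cue(name=name, categories=categories, likelihoods=likelihoods))
    population = doc.get("population")
    if population is not None and (not isinstance(population, int) or isinstance(population, bool)):
        raise MalformedInputError("population: expected an integer")
    task = DiagnosticTask(
        hypothesis_space=HypothesisSpace(labels=labels, priors=priors),
        cues=tuple(cues),
        reference_population=population,
    )
    violations = validate_task(task)
    if violations:
        raise TaskValidationError(violations)
    return task


def dump_task(task: DiagnosticTask) -> str:
    """Serialize a task to task-spec JSON (inverse of :func:`load_task`)."""
    doc = {
        "hypotheses": [
            {"label": h, "prior": _num_to_json(task.hypothesis_space.priors[h])}
            for h in task.hypothesis_space.labels
        ],
        "cues": [
            {
                "name": cue.name,
                "categories": list(cue.categories),
                "likelihoods": [
                    {
                        "hypothesis": h,
                        **({"context": dict(sorted(ctx))} if ctx else {}),
                        "distribution": {c: _num_to_json(dist[c]) for c in cue.categories},
                    }
                    for (h, ctx), dist in cue.likelihoods.items()
                ],
            }
            for cue in task.cues
        ],
    }
    if task.reference_population is not None:
        doc["population"] = task.reference_population
    return json.dumps(doc, indent=2)


# ---------------------------------------------------------------------------
# natural frequency trees

HYPOTHESIS_LAYER = "hypothesis"


@dataclass(frozen=True)
class TreeLayer:
    """What one tree layer partitions on, and the branch order."""

    on: str  # HYPOTHESIS_LAYER or a cue name (for cue-first trees, "outcome" at the leaves)
    categories: tuple[str, ...]


@dataclass(frozen=True)
class NaturalFrequencyTree:
    """A reference population decomposed into counts, layer by layer.

    ``orientation`` is ``"hypothesis-first"`` (hypotheses at the top layer,
    cue values below) or ``"cue-first"`` (cue values at the top, the outcome
    at the leaves).  ``nodes`` maps each path of branch labels from the root
    to its count; the empty path is the root and carries N.  Counts are
    integers except in exact-rational trees, where they are Fractions.
    """

    orientation: str
    root_count: Number
    layers: tuple[TreeLayer, ...]
    nodes: Mapping[tuple[str, ...], Number]

    def count(self, path: Sequence[str]) -> Number:
        path = tuple(path)
        if path not in self.nodes:
            raise DomainError(f"no tree node at path {path!r}")
        return self.nodes[path]

    def paths(self):
        """All node paths in deterministic order: by layer, then branch order."""
        out = [()]
        frontier = [()]
        for layer in self.layers:
            frontier = [p + (c,) for p in frontier for c in layer.categories if p + (c,) in self.nodes]
            out.extend(frontier)
        return out

    def violations(self) -> list[str]:
        out = []
        if self.orientation not in ("hypothesis-first", "cue-first"):
            out.append(f"orientation: unknown value {self.orientation!r}")
        if self.root_count < 0:
            out.append("root_count: negative")
        if self.nodes.get((), None) != self.root_count:
            out.append("root node count does not equal root_count")
        valid_paths = set(self.paths())
        for path in self.nodes:
            if path not in valid_paths:
                out.append(f"node {path!r}: label not valid for its layer")
        for depth, layer in enumerate(self.layers):
            parents = [p for p in valid_paths if len(p) == depth]
            for parent in parents:
                children = [self.nodes[parent + (c,)] for c in layer.categories
                            if parent + (c,) in self.nodes]
                if children and sum(children) != self.nodes[parent]:
                    out.append(
                        f"node {parent!r}: children sum to {sum(children)}, "
                        f"not {self.nodes[parent]}"
                    )
        for path, count in self.nodes.items():
            if count < 0:
                out.append(f"node {path!r}: negative count")
        return out


def write_tree_json(tree: NaturalFrequencyTree) -> str:
    doc = {
        "orientation": tree.orientation,
        "root_count": _num_to_json(tree.root_count),
        "layers": [{"on": l.on, "categories": list(l.categories)} for l in tree.layers],
        "nodes": [
            {"path": list(p), "count": _num_to_json(tree.nodes[p])} for p in tree.paths()
        ],
    }
    return json.dumps(doc, indent=2)


def load_tree(text: str) -> NaturalFrequencyTree:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise MalformedInputError(f"invalid JSON: {exc}") from exc
    try:
        tree = NaturalFrequencyTree(
            orientation=doc["orientation"],
            root_count=_as_number(doc["root_count"]),
            layers=tuple(TreeLayer(on=l["on"], categories=tuple(l["categories"]))
                         for l in doc["layers"]),
            nodes={tuple(n["path"]): _as_number(n["count"]) for n in doc["nodes"]},
        )
    except (KeyError, TypeError) as exc:
        raise MalformedInputError(f"tree: missing or malformed field ({exc})") from exc
    violations = tree.violations()
    if violations:
        raise TaskValidationError(violations)
    return tree


def write_tree_dot(tree: NaturalFrequencyTree) -> str:
    """Render the tree as Graphviz DOT text, one node per count.

    Node order is deterministic: layer by layer, branches in declared
    category order.  Labels read ``branch label: count`` (the root reads
    ``N: count``).
    """
    ids = {path: f"n{i}" for i, path in enumerate(tree.paths())}
    lines = ["digraph natural_frequency_tree {", "  rankdir=TB;"]
    for path, node_id in ids.items():
        label = "N" if not path else path[-1]
        count = tree.nodes[path]
        lines.append(f'  {node_id} [label="{label}: {count}"];')
    for path, node_id in ids.items():
        if path:
            lines.append(f"  {ids[path[:-1]]} -> {node_id};")
    lines.append("}")
    return "\n".join(lines)
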