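"""Boolean cue merging and pair-comparison cue validity.

In a pair-comparison environment, objects carry binary cue values and a
numeric criterion (e.g. which of two patients has the higher blood
pressure).  A cue's *validity* is the proportion of correct inferences:
over all object pairs with distinct criterion values in which the cue
discriminates, the fraction where the cue-positive object has the higher
criterion.  Cues that are individually weak can be merged with Boolean
algebra (AND/OR/XOR) into a derived cue that is far more valid than
either component when the environment has the right dependence structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Union

import numpy as np
import pandas as pd

from .errors import DomainError, MalformedInputError, UndefinedValidityError
from .fft import OUTCOME, CaseDataset

CRITERION = "criterion"

_BOOL_OPS = {
    "AND": lambda a, b: a & b,
    "OR": lambda a, b: a | b,
    "XOR": lambda a, b: a ^ b,
}


@dataclass
class PairComparisonEnvironment:
    """Objects with binary (0/1) cue values and a numeric criterion."""

    df: pd.DataFrame
    cue_names: tuple[str, ...]

    def __post_init__(self):
        if len(self.df) < 2:
            raise DomainError("environment needs at least 2 objects")
        if CRITERION not in self.df.columns:
            raise DomainError("environment is missing the criterion column")
        if self.df[CRITERION].nunique() < 2:
            raise DomainError("no pair of objects with distinct criterion values")

    def to_csv(self) -> str:
        cols = list(self.cue_names) + [CRITERION]
        return self.df[cols].to_csv(index=False)

    @classmethod
    def from_csv(cls, text: str) -> "PairComparisonEnvironment":
        try:
            df = pd.read_csv(StringIO(text))
        except Exception as exc:
            raise MalformedInputError(f"invalid CSV: {exc}") from exc
        if CRITERION not in df.columns:
            raise MalformedInputError("CSV must have a 'criterion' column")
        return cls(df=df, cue_names=tuple(c for c in df.columns if c != CRITERION))


MergeTarget = Union[CaseDataset, PairComparisonEnvironment]


def merge_cues(data: MergeTarget, cue_a: str, cue_b: str, op: str) -> MergeTarget:
    """Add a derived cue combining two binary cues with Boolean algebra.

    The new column is named ``{cue_a}_{op}_{cue_b}``; its positive polarity
    is "combination true".  Original columns are untouched.
    """
    if op not in _BOOL_OPS:
        raise DomainError(f"unknown Boolean op {op!r}; expected AND, OR or XOR")
    name = f"{cue_a}_{op}_{cue_b}"
    if isinstance(data, PairComparisonEnvironment):
        for cue in (cue_a, cue_b):
            if cue not in data.cue_names:
                raise DomainError(f"unknown cue {cue!r}")
            if not set(data.df[cue].unique()) <= {0, 1}:
                raise DomainError(f"cue {cue!r} is not binary 0/1")
        df = data.df.copy()
        df[name] = _BOOL_OPS[op](df[cue_a].astype(bool), df[cue_b].astype(bool)).astype(int)
        return PairComparisonEnvironment(df=df, cue_names=data.cue_names + (name,))
    if isinstance(data, CaseDataset):
        for cue in (cue_a, cue_b):
            if cue not in data.cue_names:
                raise DomainError(f"unknown cue {cue!r}")
            if not data.is_binary(cue):
                raise DomainError(f"cue {cue!r} is not binary")
            if cue not in data.positive_values:
                raise DomainError(f"cue {cue!r} has no declared positive value")
        a = data.df[cue_a] == data.positive_values[cue_a]
        b = data.df[cue_b] == data.positive_values[cue_b]
        df = data.df.copy()
        df[name] = np.where(_BOOL_OPS[op](a, b), "yes", "no")
        return CaseDataset(
            df=df,
            cue_names=data.cue_names + (name,),
            categories={**data.categories, name: ("yes", "no")},
            positive_values={**data.positive_values, name: "yes"},
            positive_outcome=data.positive_outcome,
        )
    raise DomainError(f"cannot merge cues on {type(data).__name__}")


def cue_validity(env: PairComparisonEnvironment, cue: str) -> float:
    """Proportion of discriminating pairs in which the cue points correctly.

    Pairs with tied criterion values are excluded; pairs where the cue does
    not discriminate (same value on both objects) are excluded.  Raises
    :class:`UndefinedValidityError` when no pair remains.
    """
    if cue not in env.df.columns:
        raise DomainError(f"unknown cue {cue!r}")
    v = env.df[cue].to_numpy()
    if not set(np.unique(v)) <= {0, 1}:
        raise DomainError(f"cue {cue!r} is not binary 0/1")
    c = env.df[CRITERION].to_numpy(dtype=float)
    c_pos = c[v == 1]
    c_neg = c[v == 0]
    if len(c_pos) == 0 or len(c_neg) == 0:
        raise UndefinedValidityError(f"cue {cue!r} never discriminates")
    diff = c_pos[:, None] - c_neg[None, :]
    correct = int((diff > 0).sum())
    wrong = int((diff < 0).sum())
    if correct + wrong == 0:
        raise UndefinedValidityError(f"cue {cue!r}: all discriminating pairs have tied criteria")
    return correct / (correct + wrong)
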