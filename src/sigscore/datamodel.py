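"""Core domain types shared across the package.

The expression matrix itself is a plain :class:`pandas.DataFrame` with
features on the rows (unique index) and samples on the columns (unique
header) — the container every scorer consumes.  :func:`validate_expression`
enforces the invariants once, at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Signature",
    "RunConfig",
    "SignificanceResult",
    "NullDistribution",
    "validate_expression",
    "SCORE_TABLE_COLUMNS",
]

#: Column order of the long-format score table.
SCORE_TABLE_COLUMNS = (
    "sample_id",
    "signature",
    "scorer",
    "transform",
    "score",
    "n_features_used",
)

STRATEGIES = ("none", "data_with_replacement", "data_without_replacement", "random_signatures")
ALTERNATIVES = ("greater", "less", "two_sided")


@dataclass(frozen=True)
class Signature:
    """A named, ordered set of molecular features with optional weights.

    Weights default to 1.0 per feature; signed weights let the weighted-sum
    and weighted-mean scorers encode up/down-regulated members.
    """

    name: str
    features: tuple[str, ...]
    weights: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("signature name must be non-empty")
        feats = tuple(str(f) for f in self.features)
        if len(feats) == 0:
            raise ValueError(f"signature {self.name!r}: feature list is empty")
        if len(set(feats)) != len(feats):
            seen, dup = set(), None
            for f in feats:
                if f in seen:
                    dup = f
                    break
                seen.add(f)
            raise ValueError(f"signature {self.name!r}: duplicate feature {dup!r}")
        object.__setattr__(self, "features", feats)
        if self.weights is not None:
            w = tuple(float(x) for x in self.weights)
            if len(w) != len(feats):
                raise ValueError(
                    f"signature {self.name!r}: {len(w)} weights for {len(feats)} features"
                )
            object.__setattr__(self, "weights", w)

    @property
    def size(self) -> int:
        return len(self.features)

    def weight_array(self) -> np.ndarray:
        if self.weights is None:
            return np.ones(len(self.features))
        return np.asarray(self.weights, dtype=float)


@dataclass
class RunConfig:
    """Configuration of a full scoring run (the `score` entry point)."""

    scorer_ids: Sequence[str]
    transform_id: str = "identity"
    transform_params: dict = field(default_factory=dict)
    scorer_params: dict = field(default_factory=dict)
    strategy: str = "none"
    B: int = 100
    seed: int = 0
    alternative: str = "two_sided"
    conf_level: float = 0.95
    parallel: bool = False
    n_jobs: int = 2
    exclude_signature: bool = False

    def __post_init__(self) -> None:
        if not self.scorer_ids:
            raise ValueError("at least one scorer id is required")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; valid: {STRATEGIES}")
        if self.strategy != "none" and self.B < 1:
            raise ValueError("B must be >= 1 when a resampling strategy is selected")
        if self.alternative not in ALTERNATIVES:
            raise ValueError(f"unknown alternative {self.alternative!r}; valid: {ALTERNATIVES}")
        if not (0.0 < self.conf_level < 1.0):
            raise ValueError("conf_level must lie in (0, 1)")

    def copy(self) -> "RunConfig":
        return replace(self)


@dataclass
class SignificanceResult:
    """Inferential summary of an observed score against its empirical null."""

    observed: float
    asl: float
    se: float
    ci_low: float
    ci_high: float
    conf_level: float
    alternative: str
    B_effective: int


@dataclass
class NullDistribution:
    """Replicate scores for one (signature, scorer, transform) over all samples.

    ``replicates`` is a (n_samples × B) DataFrame: row index = sample ids,
    one column per replicate.  Provenance (strategy, seed) is recorded
    exactly as used so the null can be regenerated.
    """

    signature_name: str
    scorer_id: str
    transform_id: str
    strategy: str
    B: int
    seed: int
    replicates: pd.DataFrame

    def __post_init__(self) -> None:
        if self.replicates.shape[1] != self.B:
            raise ValueError(
                f"replicate matrix has {self.replicates.shape[1]} columns, expected B={self.B}"
            )

    def for_sample(self, sample_id: str) -> np.ndarray:
        return self.replicates.loc[sample_id].to_numpy(dtype=float)


def validate_expression(df: pd.DataFrame) -> pd.DataFrame:
    """Check expression-matrix invariants and coerce values to float.

    Feature ids (index) and sample ids (columns) must be unique and
    non-empty; all cells must be numeric or NaN.
    """
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError("expression matrix must have at least one feature and one sample")
    idx = df.index.astype(str)
    cols = df.columns.astype(str)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise ValueError(f"duplicate feature id {dup!r}")
    if cols.has_duplicates:
        dup = cols[cols.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r}")
    if any(x == "" for x in idx) or any(x == "" for x in cols):
        raise ValueError("empty feature or sample id")
    out = df.copy()
    out.index = idx
    out.columns = cols
    try:
        out = out.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric value in expression matrix: {exc}") from exc
    return out
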