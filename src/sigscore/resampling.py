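"""Empirical null distributions via data resampling and random signatures.

Two complementary strategies:

* **data resampling** — each sample column's values are resampled *across
  features*, with replacement (i.i.d. draws from the column) or without
  (a uniform permutation).  Feature identity is destroyed while each
  sample's value distribution is preserved (exactly so for permutation).
  The data transform is re-applied to every perturbed matrix, so the null
  flows through the same pipeline as the observed score.
* **random signatures** — sets of features matching the used signature
  size are drawn uniformly without replacement from a background pool
  (default: all matrix features), and scored on the original data.

Replicate ``r`` draws its generator from the seed list ``[*key, r]``
(numpy ``SeedSequence`` entropy), so results are bit-identical regardless
of execution order or worker count.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import NullDistribution, Signature
from .scorers import ScorerParams, feature_id_rank, score_values, subset_signature
from .transform import make_transform

__all__ = [
    "sample_data",
    "sample_data_values",
    "random_signatures",
    "replicate_rng",
    "build_null",
]


def replicate_rng(key: Sequence[int], r: int) -> np.random.Generator:
    """Deterministic, order-independent generator for replicate ``r``."""
    return np.random.default_rng([int(x) & 0x7FFFFFFF for x in (*key, r)])


def sample_data_values(
    values: np.ndarray, with_replacement: bool, rng: np.random.Generator
) -> np.ndarray:
    """Resample each column independently across features (numpy core)."""
    n_feat, n_samp = values.shape
    out = np.empty_like(values)
    for j in range(n_samp):
        if with_replacement:
            idx = rng.integers(0, n_feat, size=n_feat)
        else:
            idx = rng.permutation(n_feat)
        out[:, j] = values[idx, j]
    return out


def sample_data(
    m: pd.DataFrame, with_replacement: bool, rng: np.random.Generator
) -> pd.DataFrame:
    """Perturb the matrix by within-column feature-value resampling.

    Dimensions and ids are unchanged; without replacement each output
    column is a permutation of its input column.
    """
    return pd.DataFrame(
        sample_data_values(m.to_numpy(dtype=float), with_replacement, rng),
        index=m.index,
        columns=m.columns,
    )


def random_signatures(
    pool: Sequence[str],
    k: int,
    B: int,
    rng: np.random.Generator,
    name_prefix: str = "random",
) -> list[Signature]:
    """Draw B random signatures of exactly k distinct features from a pool."""
    pool = list(pool)
    if k < 1:
        raise ValueError("signature size k must be >= 1")
    if k > len(pool):
        raise ValueError(f"cannot draw k={k} features from a pool of {len(pool)}")
    out = []
    arr = np.asarray(pool, dtype=object)
    for b in range(B):
        idx = rng.choice(len(arr), size=k, replace=False)
        out.append(Signature(name=f"{name_prefix}_{b}", features=tuple(arr[idx])))
    return out


def build_null(
    m: pd.DataFrame,
    s: Signature,
    scorer_id: str,
    strategy: str,
    B: int,
    seed: int,
    transform_id: str = "identity",
    step_thresholds: Optional[Sequence[float]] = None,
    params: Optional[ScorerParams] = None,
    exclude_signature: bool = False,
    seed_key: Optional[Sequence[int]] = None,
) -> NullDistribution:
    """Compute B replicate scores per sample under a resampling strategy.

    Data strategies rescore the original signature on perturbed data (the
    transform re-applied per replicate); the random-signature strategy
    rescores same-size random feature sets on the once-transformed original
    data.  Scorer failures within a replicate degrade to missing scores.
    """
    if strategy not in (
        "data_with_replacement",
        "data_without_replacement",
        "random_signatures",
    ):
        raise ValueError(f"unknown resampling strategy {strategy!r}")
    if B < 1:
        raise ValueError("B must be >= 1")
    params = params or ScorerParams()
    transform = make_transform(transform_id, step_thresholds)
    key = tuple(seed_key) if seed_key is not None else (seed,)

    values = m.to_numpy(dtype=float)
    _, used, weights = subset_signature(m, s)
    indexer = pd.Index(m.index)
    row_idx = indexer.get_indexer(used)
    id_rank = feature_id_rank(m.index)
    n_samp = values.shape[1]

    reps = np.full((n_samp, B), np.nan)
    n_failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if strategy == "random_signatures":
            tvalues = transform(values)
            pool_idx = np.arange(values.shape[0])
            if exclude_signature:
                pool_idx = np.setdiff1d(pool_idx, row_idx)
            k = len(row_idx)
            if k > len(pool_idx):
                raise ValueError(
                    f"cannot draw k={k} features from a background pool of {len(pool_idx)}"
                )
            for r in range(B):
                rng = replicate_rng(key, r)
                ridx = pool_idx[rng.choice(len(pool_idx), size=k, replace=False)]
                try:
                    reps[:, r] = score_values(
                        tvalues, ridx, np.ones(k), scorer_id, params, id_rank=id_rank
                    )
                except (ValueError, np.linalg.LinAlgError):
                    n_failed += 1
        else:
            with_replacement = strategy == "data_with_replacement"
            for r in range(B):
                rng = replicate_rng(key, r)
                perturbed = sample_data_values(values, with_replacement, rng)
                try:
                    reps[:, r] = score_values(
                        transform(perturbed),
                        row_idx,
                        weights,
                        scorer_id,
                        params,
                        id_rank=id_rank,
                    )
                except (ValueError, np.linalg.LinAlgError):
                    n_failed += 1
    if n_failed:
        warnings.warn(
            f"{n_failed} of {B} replicates failed for scorer {scorer_id!r}; "
            "recorded as missing"
        )
    return NullDistribution(
        signature_name=s.name,
        scorer_id=scorer_id,
        transform_id=transform_id,
        strategy=strategy,
        B=B,
        seed=seed,
        replicates=pd.DataFrame(reps, index=m.columns, columns=range(B)),
    )
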