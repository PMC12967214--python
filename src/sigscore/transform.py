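"""Built-in data transformations applied to the full matrix before scoring.

Three transforms are provided besides the identity:

* ``step`` — each value becomes the count of thresholds ≤ it, i.e. a
  discretization into ``len(thresholds)+1`` ordered levels (left-closed
  intervals).
* ``quantile_norm`` — classic rank-based quantile normalization across
  sample columns: every column is forced onto the per-rank cross-column
  mean distribution; ties receive the mean reference value over their rank
  span.
* ``zscore`` — per-feature standardization across samples (sample SD,
  ``ddof=1``); constant rows become all zeros with a warning.

Transforms operate on the *full* matrix, before signature subsetting,
because rank- and variance-based statistics need the complete feature
background.  Each has a numpy core (``*_values``) used by the resampling
fast path, plus a DataFrame wrapper.
"""

from __future__ import annotations

import warnings
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "transform_step",
    "transform_quantile_norm",
    "transform_zscore",
    "make_transform",
    "TRANSFORM_IDS",
]

TRANSFORM_IDS = ("identity", "step", "quantile_norm", "zscore")


# ---------------------------------------------------------------------------
# numpy cores

def step_values(values: np.ndarray, thresholds: Sequence[float]) -> np.ndarray:
    t = np.asarray(thresholds, dtype=float)
    if t.size == 0:
        raise ValueError("step transform needs at least one threshold")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("step thresholds must be strictly increasing")
    out = np.full(values.shape, np.nan)
    finite = np.isfinite(values)
    # count of thresholds t_i <= x  ==  right-sided insertion index
    out[finite] = np.searchsorted(t, values[finite], side="right").astype(float)
    return out


def quantile_norm_values(values: np.ndarray) -> np.ndarray:
    if np.isnan(values).any():
        raise ValueError(
            "quantile normalization requires a complete matrix; impute missing values first"
        )
    n_feat, n_samp = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)  # per-rank cross-column mean
    out = np.empty_like(values, dtype=float)
    for j in range(n_samp):
        col = values[:, j]
        ranks = np.empty(n_feat, dtype=float)
        ranks[order[:, j]] = reference
        # ties: average the reference values over the tied rank span
        uniq, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        if len(uniq) < n_feat:
            sums = np.bincount(inverse, weights=ranks)
            ranks = (sums / counts)[inverse]
        out[:, j] = ranks
    return out


def zscore_values(values: np.ndarray, warn: bool = True) -> np.ndarray:
    out = np.zeros_like(values, dtype=float)
    out[np.isnan(values)] = np.nan
    n_ok = np.sum(~np.isnan(values), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(values, axis=1)
        sd = np.nanstd(values, axis=1, ddof=1)
    degenerate = (n_ok < 2) | (sd == 0) | ~np.isfinite(sd)
    ok = ~degenerate
    if ok.any():
        out[ok] = (values[ok] - mu[ok, None]) / sd[ok, None]
    if degenerate.any() and warn:
        warnings.warn(
            f"{int(degenerate.sum())} feature row(s) with zero variance or <2 values "
            "standardized to all zeros"
        )
    # degenerate rows: zeros where observed, NaN preserved (already set)
    return out


# ---------------------------------------------------------------------------
# DataFrame wrappers

def transform_step(m: pd.DataFrame, thresholds: Sequence[float]) -> pd.DataFrame:
    """Replace each finite value by the number of thresholds ≤ it."""
    return pd.DataFrame(
        step_values(m.to_numpy(dtype=float), thresholds), index=m.index, columns=m.columns
    )


def transform_quantile_norm(m: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize sample columns onto the per-rank mean distribution."""
    return pd.DataFrame(
        quantile_norm_values(m.to_numpy(dtype=float)), index=m.index, columns=m.columns
    )


def transform_zscore(m: pd.DataFrame) -> pd.DataFrame:
    """Standardize every feature row to mean 0, sample SD 1 across samples."""
    return pd.DataFrame(
        zscore_values(m.to_numpy(dtype=float)), index=m.index, columns=m.columns
    )


def make_transform(
    transform_id: str, step_thresholds: Optional[Sequence[float]] = None
) -> Callable[[np.ndarray], np.ndarray]:
    """Return the numpy-core transform callable for an id.

    The callable maps a values array to a transformed array of the same
    shape; ``identity`` is a no-op.
    """
    if transform_id in (None, "identity", "none"):
        return lambda values: values
    if transform_id == "step":
        if step_thresholds is None or len(step_thresholds) == 0:
            raise ValueError("step transform requires thresholds")
        thr = tuple(float(t) for t in step_thresholds)
        return lambda values: step_values(values, thr)
    if transform_id == "quantile_norm":
        return quantile_norm_values
    if transform_id == "zscore":
        return zscore_values
    raise ValueError(f"unknown transform {transform_id!r}; valid: {TRANSFORM_IDS}")
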