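"""Summary-score computations: (matrix, signature) → one score per sample.

Two families share a uniform entry point (:func:`score_signature`):

* **Column scorers** reduce the signature's values within one sample
  column: total quantity (sum, weightedSum), central tendency (mean,
  weightedMean, trimmedMean, median, mode, midrange, midhinge, trimean,
  iqm) and dispersion (iqr, mad, aad).  Quartiles are type-7
  (linear-interpolation) throughout.
* **Matrix scorers** need the whole matrix or the signature submatrix at
  once: combinedZ (sum of per-feature z-values over √k), pca1 (sample
  coordinates on the first principal axis), plage (first right singular
  vector of the row-standardized submatrix), ssgsea (rank-weighted
  running-sum enrichment within each sample) and gsva (kernel-CDF →
  symmetric rank statistic → KS-like random walk).

Missing values: column scorers drop NaNs per sample (``na_rm``), reducing
the effective feature count; a sample with no usable values gets a missing
score.  pca1/plage drop feature rows containing NaNs with a warning;
ssgsea/gsva require a complete matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .datamodel import Signature
from .transform import zscore_values

__all__ = [
    "ScorerParams",
    "COLUMN_SCORERS",
    "MATRIX_SCORERS",
    "ALL_SCORERS",
    "subset_signature",
    "score_column",
    "score_signature",
    "combined_z_scores",
    "pca1_scores",
    "plage_scores",
    "ssgsea_scores",
    "gsva_scores",
]


@dataclass
class ScorerParams:
    """Tunable scorer parameters with field-standard defaults."""

    trim: float = 0.1            # trimmedMean: fraction dropped from each end
    ssgsea_alpha: float = 0.25   # rank-weight exponent
    ssgsea_normalize: bool = False  # divide by max-min across samples
    gsva_tau: float = 1.0        # rank-statistic exponent in the random walk
    mad_constant: bool = False   # multiply MAD by 1.4826 (normal consistency)
    na_rm: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.trim < 0.5):
            raise ValueError("trim fraction must lie in [0, 0.5)")
        if self.ssgsea_alpha <= 0:
            raise ValueError("ssgsea alpha must be > 0")


# ---------------------------------------------------------------------------
# column scorers


def _quartiles(v: np.ndarray) -> tuple[float, float, float]:
    q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # numpy default = type 7
    return float(q1), float(q2), float(q3)


def _mode(v: np.ndarray) -> float:
    vals, counts = np.unique(v, return_counts=True)
    if len(vals) == len(v) and len(v) > 1:
        warnings.warn("mode of all-distinct values falls back to the minimum")
    return float(vals[np.argmax(counts)])  # np.unique sorts: ties -> smallest


def _trimmed_mean(v: np.ndarray, g: float) -> float:
    n = len(v)
    cut = int(np.floor(g * n))  # g < 0.5 guarantees 2*cut < n
    s = np.sort(v)
    return float(s[cut : n - cut].mean())


def _iqm(v: np.ndarray) -> float:
    """Interquartile mean: fractional-weight trimmed mean at g = 0.25."""
    n = len(v)
    if n == 1:
        return float(v[0])
    s = np.sort(v)
    t = 0.25 * n               # amount trimmed from each end
    f = int(np.floor(t))
    frac = t - f
    w = np.ones(n)
    w[:f] = 0.0
    w[n - f :] = 0.0
    w[f] -= frac               # end observations get fractional weight
    w[n - 1 - f] -= frac
    return float(np.dot(w, s) / w.sum())


def _score_plain(v: np.ndarray, w: np.ndarray, scorer_id: str, p: ScorerParams) -> float:
    if scorer_id == "sum":
        return float(v.sum())
    if scorer_id == "weightedSum":
        return float(np.dot(w, v))
    if scorer_id == "mean":
        return float(v.mean())
    if scorer_id == "weightedMean":
        sw = w.sum()
        if sw == 0:
            warnings.warn("weightedMean with zero total weight yields a missing score")
            return float("nan")
        return float(np.dot(w, v) / sw)
    if scorer_id == "trimmedMean":
        return _trimmed_mean(v, p.trim)
    if scorer_id == "median":
        return float(np.median(v))
    if scorer_id == "mode":
        return _mode(v)
    if scorer_id == "midrange":
        return float((v.min() + v.max()) / 2.0)
    if scorer_id == "midhinge":
        q1, _, q3 = _quartiles(v)
        return (q1 + q3) / 2.0
    if scorer_id == "trimean":
        q1, q2, q3 = _quartiles(v)
        return (q1 + 2.0 * q2 + q3) / 4.0
    if scorer_id == "iqr":
        q1, _, q3 = _quartiles(v)
        return q3 - q1
    if scorer_id == "iqm":
        return _iqm(v)
    if scorer_id == "mad":
        m = float(np.median(np.abs(v - np.median(v))))
        return m * 1.4826 if p.mad_constant else m
    if scorer_id == "aad":
        return float(np.mean(np.abs(v - v.mean())))
    raise ValueError(f"unknown column scorer {scorer_id!r}")


COLUMN_SCORERS = (
    "sum",
    "weightedSum",
    "mean",
    "trimmedMean",
    "weightedMean",
    "median",
    "mode",
    "midrange",
    "midhinge",
    "trimean",
    "iqr",
    "iqm",
    "mad",
    "aad",
)

MATRIX_SCORERS = ("combinedZ", "pca1", "plage", "ssgsea", "gsva")

ALL_SCORERS = COLUMN_SCORERS + MATRIX_SCORERS


def score_column(
    values: Sequence[float],
    weights: Optional[Sequence[float]],
    scorer_id: str,
    params: Optional[ScorerParams] = None,
) -> float:
    """Score one sample's signature values with a column scorer.

    NaNs are dropped (with their weights) when ``na_rm`` is set; an empty
    vector after removal yields NaN.
    """
    p = params or ScorerParams()
    v = np.asarray(values, dtype=float)
    w = np.ones(len(v)) if weights is None else np.asarray(weights, dtype=float)
    if p.na_rm:
        keep = ~np.isnan(v)
        v, w = v[keep], w[keep]
    elif np.isnan(v).any():
        return float("nan")
    if len(v) == 0:
        return float("nan")
    return _score_plain(v, w, scorer_id, p)


# ---------------------------------------------------------------------------
# signature / matrix plumbing


def subset_signature(
    m: pd.DataFrame, s: Signature
) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """Restrict the matrix to the signature's features, in signature order.

    Returns (submatrix, used feature ids, aligned weights); warns about
    signature features absent from the matrix and errors if none remain.
    """
    index = set(m.index)
    used = [f for f in s.features if f in index]
    missing = [f for f in s.features if f not in index]
    if not used:
        raise ValueError(f"signature {s.name!r} shares no features with the matrix")
    if missing:
        warnings.warn(
            f"signature {s.name!r}: {len(missing)} feature(s) absent from the matrix: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    w = s.weight_array()
    keep = np.array([f in index for f in s.features])
    return m.loc[used], used, w[keep]


def _orient_sign(scores: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip the score vector so it correlates non-negatively with reference."""
    s = scores - scores.mean()
    r = reference - reference.mean()
    c = float(np.dot(s, r))
    return -scores if c < 0 else scores


def _drop_nan_rows(sub: np.ndarray, scorer_id: str) -> np.ndarray:
    bad = np.isnan(sub).any(axis=1)
    if bad.any():
        warnings.warn(
            f"{scorer_id}: dropping {int(bad.sum())} signature row(s) with missing values"
        )
        sub = sub[~bad]
    if sub.shape[0] == 0:
        raise ValueError(f"{scorer_id}: no complete signature rows")
    return sub


def combined_z_scores(values: np.ndarray, row_idx: np.ndarray) -> np.ndarray:
    """Sum of row-standardized signature values per sample over √k.

    k counts the non-missing z entries of each sample; constant rows
    standardize to 0 and still count.  If every used row is constant the
    scores are missing.
    """
    z = zscore_values(values, warn=False)[row_idx]
    src = values[row_idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_sd = np.nanstd(src, axis=1, ddof=1)
    if np.all((row_sd == 0) | ~np.isfinite(row_sd)):
        warnings.warn("combinedZ: all signature rows are constant; scores are missing")
        return np.full(values.shape[1], np.nan)
    k = np.sum(~np.isnan(z), axis=0).astype(float)
    total = np.nansum(z, axis=0)
    out = np.full(values.shape[1], np.nan)
    ok = k > 0
    out[ok] = total[ok] / np.sqrt(k[ok])
    return out


def pca1_scores(sub: np.ndarray) -> np.ndarray:
    """Sample coordinates on the first principal axis of the centered submatrix.

    Sign is oriented so the scores correlate non-negatively with the
    per-sample mean of the submatrix.
    """
    sub = _drop_nan_rows(sub, "pca1")
    ref = sub.mean(axis=0)
    centered = sub - sub.mean(axis=1, keepdims=True)
    if not np.any(centered):
        warnings.warn("pca1: zero-variance submatrix; scores are all zero")
        return np.zeros(sub.shape[1])
    # samples as observations: coordinates = s1 * v1 from the SVD of the
    # centered feature × sample matrix
    u, sv, vt = np.linalg.svd(centered, full_matrices=False)
    scores = sv[0] * vt[0]
    return _orient_sign(scores, ref)


def plage_scores(sub: np.ndarray) -> np.ndarray:
    """First right singular vector (unit norm) of the row-standardized submatrix."""
    sub = _drop_nan_rows(sub, "plage")
    z = zscore_values(sub, warn=False)
    sd = np.std(sub, axis=1, ddof=1)
    if np.all(sd == 0):
        warnings.warn("plage: all signature rows constant; scores are missing")
        return np.full(sub.shape[1], np.nan)
    u, sv, vt = np.linalg.svd(z, full_matrices=False)
    return _orient_sign(vt[0].copy(), z.mean(axis=0))


def _check_complete(values: np.ndarray, scorer_id: str) -> None:
    if np.isnan(values).any():
        raise ValueError(f"{scorer_id} requires a complete matrix (no missing values)")


def _walk_order(col: np.ndarray, id_rank: np.ndarray) -> np.ndarray:
    """Feature order for the running sum: descending value, ties by ascending id."""
    return np.lexsort((id_rank, -col))


def ssgsea_scores(
    values: np.ndarray,
    in_mask: np.ndarray,
    id_rank: np.ndarray,
    alpha: float = 0.25,
    normalize: bool = False,
) -> np.ndarray:
    """Single-sample rank-weighted enrichment score per sample.

    Within each sample, features are ranked ascending by expression (top
    feature gets rank N); walking the descending-ordered list, the score is
    the running-sum difference between the rank^alpha-weighted ECDF of
    in-signature features and the unweighted ECDF of the rest, summed over
    all positions.  Expression ties break by ascending feature-id order.
    """
    _check_complete(values, "ssgsea")
    n_feat, n_samp = values.shape
    k = int(in_mask.sum())
    if k == 0:
        raise ValueError("ssgsea: signature has no features in the matrix")
    if k == n_feat:
        raise ValueError("ssgsea: signature covers every matrix feature")
    scores = np.empty(n_samp)
    for j in range(n_samp):
        order = _walk_order(values[:, j], id_rank)
        ranks = np.arange(n_feat, 0, -1, dtype=float)  # walk position i -> rank N-i
        in_ord = in_mask[order]
        w = np.where(in_ord, ranks**alpha, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~in_ord) / (n_feat - k)
        scores[j] = float(np.sum(p_in - p_out))
    if normalize:
        rng = scores.max() - scores.min()
        if rng > 0:
            scores = scores / rng
    return scores


def gsva_scores(
    values: np.ndarray,
    in_mask: np.ndarray,
    id_rank: np.ndarray,
    tau: float = 1.0,
) -> np.ndarray:
    """Kernel-CDF / rank-statistic enrichment score per sample.

    Stage 1: for each feature, a Gaussian-kernel estimate of the expression
    CDF across samples (bandwidth = sample SD / 4); constant features get
    0.5 everywhere.  Stage 2: per sample, rank the kernel statistics
    descending and form the symmetric statistic |N/2 − rank|.  Stage 3: a
    KS-like walk down the ranked list with in-signature increments t^tau
    (normalized) and out-of-signature decrements 1/(N−k); the score is the
    clamped maximum positive plus minimum negative walk deviation.
    """
    _check_complete(values, "gsva")
    n_feat, n_samp = values.shape
    if n_samp < 3:
        raise ValueError("gsva needs at least 3 samples")
    k = int(in_mask.sum())
    if k == 0 or k == n_feat:
        raise ValueError("gsva: signature must be a strict non-empty subset of features")

    sd = np.std(values, axis=1, ddof=1)
    mu = np.mean(values, axis=1)
    zero_sd = sd == 0
    if zero_sd.any():
        warnings.warn(
            f"gsva: {int(zero_sd.sum())} constant feature(s); kernel statistic set to 0.5"
        )
    h = np.maximum(sd / 4.0, 1e-12 * np.maximum(1.0, np.abs(mu)))
    # zhat[i, j] = mean_k Phi((x_ij - x_ik) / h_i)
    diffs = (values[:, :, None] - values[:, None, :]) / h[:, None, None]
    zhat = ndtr(diffs).mean(axis=2)
    zhat[zero_sd] = 0.5

    scores = np.empty(n_samp)
    dec = 1.0 / (n_feat - k)
    for j in range(n_samp):
        order = _walk_order(zhat[:, j], id_rank)  # descending zhat
        r = np.empty(n_feat)
        r[order] = np.arange(1, n_feat + 1)       # rank 1 = largest zhat
        t = np.abs(n_feat / 2.0 - r)
        in_ord = in_mask[order]
        t_ord = t[order]
        inc = np.where(in_ord, t_ord**tau, 0.0)
        denom = inc.sum()
        # all in-signature rank statistics zero (e.g. singleton set at the
        # middle rank): increments carry no information, contribute 0
        steps = np.where(in_ord, inc / denom if denom > 0 else 0.0, -dec)
        walk = np.cumsum(steps)
        scores[j] = max(0.0, float(walk.max())) + min(0.0, float(walk.min()))
    return scores


# ---------------------------------------------------------------------------
# uniform entry points


def score_values(
    values: np.ndarray,
    row_idx: np.ndarray,
    weights: np.ndarray,
    scorer_id: str,
    params: Optional[ScorerParams] = None,
    id_rank: Optional[np.ndarray] = None,
) -> np.ndarray:
    """numpy-level dispatcher: score every column of ``values``.

    ``row_idx`` indexes the used signature features into the rows of
    ``values``; ``id_rank`` gives the ascending-feature-id rank of every
    row (needed only by ssgsea/gsva).  Used directly by the resampling loop
    to avoid per-replicate DataFrame overhead.
    """
    p = params or ScorerParams()
    if scorer_id in COLUMN_SCORERS:
        sub = values[row_idx]
        return np.array(
            [score_column(sub[:, j], weights, scorer_id, p) for j in range(sub.shape[1])]
        )
    if scorer_id == "combinedZ":
        return combined_z_scores(values, row_idx)
    if scorer_id == "pca1":
        return pca1_scores(values[row_idx])
    if scorer_id == "plage":
        return plage_scores(values[row_idx])
    if scorer_id in ("ssgsea", "gsva"):
        if id_rank is None:
            raise ValueError(f"{scorer_id} needs the feature id_rank array")
        in_mask = np.zeros(values.shape[0], dtype=bool)
        in_mask[row_idx] = True
        if scorer_id == "ssgsea":
            return ssgsea_scores(values, in_mask, id_rank, p.ssgsea_alpha, p.ssgsea_normalize)
        return gsva_scores(values, in_mask, id_rank, p.gsva_tau)
    raise ValueError(f"unknown scorer {scorer_id!r}; valid: {ALL_SCORERS}")


def feature_id_rank(index: pd.Index) -> np.ndarray:
    """Rank of each matrix row under ascending feature-id order (tie-breaks)."""
    return np.argsort(np.argsort(index.to_numpy(dtype=str), kind="stable"), kind="stable")


def score_signature(
    m: pd.DataFrame,
    s: Signature,
    scorer_id: str,
    params: Optional[ScorerParams] = None,
) -> tuple[pd.Series, pd.Series]:
    """Score every sample of ``m`` for signature ``s`` with one scorer.

    Returns ``(scores, n_features_used)`` as Series indexed by sample id.
    The matrix is expected to be already transformed; see the orchestrator
    for transform plumbing.
    """
    p = params or ScorerParams()
    if scorer_id not in ALL_SCORERS:
        raise ValueError(f"unknown scorer {scorer_id!r}; valid: {ALL_SCORERS}")
    values = m.to_numpy(dtype=float)
    _, used, w = subset_signature(m, s)
    indexer = pd.Index(m.index)
    row_idx = indexer.get_indexer(used)
    id_rank = feature_id_rank(m.index) if scorer_id in ("ssgsea", "gsva") else None
    scores = score_values(values, row_idx, w, scorer_id, p, id_rank=id_rank)

    sub = values[row_idx]
    if scorer_id in COLUMN_SCORERS or scorer_id == "combinedZ":
        n_used = np.sum(~np.isnan(sub), axis=0)
    else:
        n_used = np.full(values.shape[1], len(used))
    return (
        pd.Series(scores, index=m.columns, name="score"),
        pd.Series(np.asarray(n_used, dtype=int), index=m.columns, name="n_features_used"),
    )
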