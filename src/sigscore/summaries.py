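"""Tabular summaries behind the standard diagnostic plots.

Every function here is a pure function of its inputs and returns a plain
DataFrame: five-number boxplot statistics per score group, scorer × scorer
correlation matrices, a wide score grid, and histogram bins for an
empirical null with the observed score echoed for overlay.  Rendering is
left to the caller (the tables drop straight into matplotlib/seaborn).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import NullDistribution

__all__ = ["box_stats", "scorer_correlation", "score_grid", "null_histogram"]


def box_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Five-number summaries (type-7 quartiles) per (signature, scorer, transform).

    Outliers are values beyond 1.5·IQR from the hinges (Tukey fences),
    returned as a comma-joined string column.
    """
    if len(table) == 0:
        raise ValueError("empty score table")
    rows = []
    for (sig, scorer, transform), grp in table.groupby(
        ["signature", "scorer", "transform"], sort=True
    ):
        v = grp["score"].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        if len(v) == 0:
            continue
        q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        outliers = np.sort(v[(v < lo) | (v > hi)])
        rows.append(
            {
                "signature": sig,
                "scorer": scorer,
                "transform": transform,
                "min": v.min(),
                "q1": q1,
                "median": q2,
                "q3": q3,
                "max": v.max(),
                "n": len(v),
                "outliers": ",".join(f"{x:.15g}" for x in outliers),
            }
        )
    return pd.DataFrame(rows)


def scorer_correlation(
    table: pd.DataFrame, method: str = "pearson", min_obs: int = 3
) -> pd.DataFrame:
    """Pairwise scorer × scorer correlations of per-sample scores.

    Computed per signature on pairwise-complete observations; pairs with
    fewer than ``min_obs`` complete samples are missing.  Output is long
    format: (signature, scorer_a, scorer_b, correlation).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    rows = []
    for sig, grp in table.groupby("signature", sort=True):
        wide = grp.pivot_table(
            index="sample_id", columns="scorer", values="score", aggfunc="first"
        )
        corr = wide.corr(method=method, min_periods=min_obs)
        for a in corr.index:
            for b in corr.columns:
                c = corr.loc[a, b]
                rows.append(
                    {
                        "signature": sig,
                        "scorer_a": a,
                        "scorer_b": b,
                        "correlation": 1.0 if a == b else c,
                    }
                )
    return pd.DataFrame(rows)


def score_grid(table: pd.DataFrame, z_scale_rows: bool = False) -> pd.DataFrame:
    """Wide score matrix: rows = signature|scorer, columns = samples.

    With ``z_scale_rows`` every complete row is standardized to mean 0,
    sample SD 1 (constant rows become zeros).
    """
    if len(table) == 0:
        raise ValueError("empty score table")
    t = table.copy()
    t["row"] = t["signature"].astype(str) + "|" + t["scorer"].astype(str)
    wide = t.pivot_table(index="row", columns="sample_id", values="score", aggfunc="first")
    if z_scale_rows:
        vals = wide.to_numpy(dtype=float)
        mu = np.nanmean(vals, axis=1, keepdims=True)
        sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
        sd[~np.isfinite(sd) | (sd == 0)] = np.inf  # constant rows -> 0
        wide = pd.DataFrame((vals - mu) / sd, index=wide.index, columns=wide.columns)
    return wide


def null_histogram(
    null: NullDistribution,
    sample_id: str,
    observed: float,
    n_bins: int = 30,
) -> pd.DataFrame:
    """Equal-width histogram of one sample's replicate scores.

    The bin range spans replicates and the observed value, so the overlay
    line always falls inside the plotted range; counts sum to the number
    of non-missing replicates.  The observed value is echoed on every row.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    reps = null.for_sample(sample_id)
    reps = reps[~np.isnan(reps)]
    if len(reps) == 0:
        raise ValueError(f"no non-missing replicates for sample {sample_id!r}")
    lo = min(reps.min(), observed)
    hi = max(reps.max(), observed)
    if lo == hi:  # degenerate: all mass at one value
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(reps, bins=n_bins, range=(lo, hi))
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "observed": observed,
            "sample_id": sample_id,
        }
    )
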