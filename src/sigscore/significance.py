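"""Inference on observed scores against empirical null distributions.

The achieved significance level (ASL) uses the add-one Monte-Carlo
estimator, ``(1 + #{extreme replicates}) / (1 + B)``, so it is a valid
p-value and never exactly zero.  Standard errors are the sample SD of the
replicates; confidence intervals are percentile intervals with type-7
quantiles.  No multiple-testing adjustment is applied — that decision is
deliberately left to the user.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import NullDistribution, SignificanceResult

__all__ = ["compute_significance", "significance_table", "SIGNIFICANCE_COLUMNS"]

SIGNIFICANCE_COLUMNS = (
    "sample_id",
    "signature",
    "scorer",
    "transform",
    "observed",
    "asl",
    "se",
    "ci_low",
    "ci_high",
    "B_effective",
)


def compute_significance(
    observed: float,
    replicates,
    alternative: str = "two_sided",
    conf_level: float = 0.95,
) -> SignificanceResult:
    """Summarize an observed score against its replicate null scores.

    Missing replicates are dropped; ``B_effective`` records how many
    remain.  ``alternative`` selects which tail counts as extreme.
    """
    r = np.asarray(replicates, dtype=float)
    r = r[~np.isnan(r)]
    b = len(r)
    if b == 0:
        raise ValueError("no non-missing replicates")
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    asl_greater = (1.0 + np.sum(r >= observed)) / (1.0 + b)
    asl_less = (1.0 + np.sum(r <= observed)) / (1.0 + b)
    if alternative == "greater":
        asl = asl_greater
    elif alternative == "less":
        asl = asl_less
    else:
        asl = min(1.0, 2.0 * min(asl_greater, asl_less))
    se = float(np.std(r, ddof=1)) if b > 1 else 0.0
    lo = (1.0 - conf_level) / 2.0
    ci_low, ci_high = np.quantile(r, [lo, 1.0 - lo])  # type-7
    return SignificanceResult(
        observed=float(observed),
        asl=float(asl),
        se=se,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        conf_level=conf_level,
        alternative=alternative,
        B_effective=b,
    )


def significance_table(
    observed: pd.DataFrame,
    nulls: Mapping[tuple, NullDistribution],
    alternative: str = "two_sided",
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """One inference row per observed score record.

    ``nulls`` maps (signature, scorer, transform) → NullDistribution.
    Records without a matching null (or with a missing observed score)
    pass through with missing inference fields; the output has exactly one
    row per observed row.
    """
    rows = []
    for rec in observed.itertuples(index=False):
        key = (rec.signature, rec.scorer, rec.transform)
        base = {
            "sample_id": rec.sample_id,
            "signature": rec.signature,
            "scorer": rec.scorer,
            "transform": rec.transform,
            "observed": rec.score,
            "asl": np.nan,
            "se": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "B_effective": 0,
        }
        null = nulls.get(key)
        if null is not None and not pd.isna(rec.score):
            reps = null.for_sample(rec.sample_id)
            if np.sum(~np.isnan(reps)) > 0:
                res = compute_significance(rec.score, reps, alternative, conf_level)
                base.update(
                    asl=res.asl,
                    se=res.se,
                    ci_low=res.ci_low,
                    ci_high=res.ci_high,
                    B_effective=res.B_effective,
                )
        rows.append(base)
    return pd.DataFrame(rows, columns=list(SIGNIFICANCE_COLUMNS))
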