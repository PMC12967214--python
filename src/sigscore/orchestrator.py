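"""Top-level driver: fan out signatures × scorers × samples.

:func:`compute_sig_scores` applies the configured transform once, scores
every (signature, scorer) pair over all samples, and — when a resampling
strategy is selected — builds the matching empirical nulls and the
significance table.  The unit of parallelism is the (signature, scorer)
task; replicate seeds derive from (master seed, signature index, scorer
index, replicate index), so parallel and serial execution are
bit-identical.

Failures are contained per task: a scorer that cannot handle a signature
yields missing scores and a collected warning instead of aborting the run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .datamodel import (
    SCORE_TABLE_COLUMNS,
    NullDistribution,
    RunConfig,
    Signature,
    validate_expression,
)
from .resampling import build_null
from .scorers import ALL_SCORERS, ScorerParams, score_signature
from .significance import significance_table
from .transform import make_transform

__all__ = ["RunResult", "compute_sig_scores"]


@dataclass
class RunResult:
    """Everything a run produced, plus the configuration that reproduces it."""

    scores: pd.DataFrame
    nulls: dict[tuple, NullDistribution] = field(default_factory=dict)
    significance: Optional[pd.DataFrame] = None
    config_echo: Optional[RunConfig] = None
    warnings: list[str] = field(default_factory=list)


def _scorer_params(config: RunConfig) -> ScorerParams:
    return ScorerParams(**config.scorer_params)


def _run_task(
    transformed: pd.DataFrame,
    raw: pd.DataFrame,
    sig: Signature,
    sig_idx: int,
    scorer_id: str,
    scorer_idx: int,
    config: RunConfig,
) -> tuple:
    """Score one (signature, scorer) pair and, if requested, its null."""
    params = _scorer_params(config)
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            scores, n_used = score_signature(transformed, sig, scorer_id, params)
        except (ValueError, np.linalg.LinAlgError) as exc:
            caught.append(f"{sig.name}/{scorer_id}: {exc}")
            scores = pd.Series(np.nan, index=transformed.columns)
            n_used = pd.Series(0, index=transformed.columns)
        null = None
        if config.strategy != "none":
            try:
                null = build_null(
                    raw,
                    sig,
                    scorer_id,
                    strategy=config.strategy,
                    B=config.B,
                    seed=config.seed,
                    transform_id=config.transform_id,
                    step_thresholds=config.transform_params.get("step_thresholds"),
                    params=params,
                    exclude_signature=config.exclude_signature,
                    seed_key=(config.seed, sig_idx, scorer_idx),
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                caught.append(f"{sig.name}/{scorer_id} null: {exc}")
        caught.extend(f"{sig.name}/{scorer_id}: {w.message}" for w in wlist)
    records = pd.DataFrame(
        {
            "sample_id": scores.index,
            "signature": sig.name,
            "scorer": scorer_id,
            "transform": config.transform_id,
            "score": scores.to_numpy(dtype=float),
            "n_features_used": n_used.to_numpy(dtype=int),
        }
    )
    return records, null, caught


def compute_sig_scores(
    m: pd.DataFrame,
    signatures: Sequence[Signature],
    config: RunConfig,
) -> RunResult:
    """Score all signatures with all configured scorers over all samples.

    Returns a :class:`RunResult` whose score table always has exactly
    |signatures| × |scorers| × |samples| records (missing scores included).
    With a resampling strategy, per-(signature, scorer) nulls and a
    significance table are attached.
    """
    m = validate_expression(m)
    unknown = [sc for sc in config.scorer_ids if sc not in ALL_SCORERS]
    if unknown:
        raise ValueError(f"unknown scorer id(s) {unknown}; valid: {list(ALL_SCORERS)}")

    run_warnings: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        transform = make_transform(
            config.transform_id, config.transform_params.get("step_thresholds")
        )
        transformed = pd.DataFrame(
            transform(m.to_numpy(dtype=float)), index=m.index, columns=m.columns
        )
    run_warnings.extend(str(w.message) for w in wlist)

    tasks = [
        (sig, si, scorer, ci)
        for si, sig in enumerate(signatures)
        for ci, scorer in enumerate(config.scorer_ids)
    ]
    runner = Parallel(n_jobs=config.n_jobs if config.parallel else 1)
    results = runner(
        delayed(_run_task)(transformed, m, sig, si, scorer, ci, config)
        for sig, si, scorer, ci in tasks
    )

    frames, nulls = [], {}
    for (sig, si, scorer, ci), (records, null, caught) in zip(tasks, results):
        frames.append(records)
        if null is not None:
            nulls[(sig.name, scorer, config.transform_id)] = null
        run_warnings.extend(caught)

    scores = pd.concat(frames, ignore_index=True).loc[:, list(SCORE_TABLE_COLUMNS)]
    sig_table = None
    if config.strategy != "none":
        sig_table = significance_table(
            scores, nulls, alternative=config.alternative, conf_level=config.conf_level
        )
    return RunResult(
        scores=scores,
        nulls=nulls,
        significance=sig_table,
        config_echo=config.copy(),
        warnings=run_warnings,
    )
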