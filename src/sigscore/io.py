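"""Readers and writers: expression matrices (TSV/CSV), GMT signature files,
and long-format score tables.

On-disk contracts
-----------------
* Expression matrix: delimited text, first row = sample ids, first column =
  feature ids.  Missing-value tokens are exactly ``NA``, the empty string,
  and ``NaN`` (case-sensitive).  Delimiter is auto-detected from the
  extension (``.tsv`` → tab, ``.csv`` → comma) unless given explicitly.
* Signatures: GMT — one set per line: name, description, member ids,
  tab-separated.  A member may carry a weight as ``id|weight`` (e.g.
  ``MYC|-1``); plain members default to weight 1.
* Score tables: long-format TSV with header
  ``sample_id  signature  scorer  transform  score  n_features_used``;
  missing scores written as ``NA``.  Numeric fields round-trip at 15
  significant digits.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .datamodel import SCORE_TABLE_COLUMNS, Signature, validate_expression

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_scores",
    "write_scores",
]

NA_TOKENS = ("NA", "", "NaN")

PathLike = Union[str, Path]


def _detect_delimiter(path: PathLike, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    suffix = Path(path).suffix.lower()
    return "," if suffix == ".csv" else "\t"


def read_expression(path: PathLike, delimiter: Optional[str] = None) -> pd.DataFrame:
    """Read a feature × sample expression matrix from delimited text.

    Raises ``ValueError`` naming the offender on duplicate ids or
    non-numeric cells.
    """
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(
        path,
        sep=sep,
        index_col=0,
        header=0,
        dtype=str,
        na_values=list(NA_TOKENS),
        keep_default_na=False,
    )
    df.index = df.index.astype(str)
    num = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric cell at feature {row!r}, sample {col!r} in {path}"
            )
        num[col] = converted
    return validate_expression(num)


def write_expression(df: pd.DataFrame, path: PathLike, delimiter: Optional[str] = None) -> None:
    """Write an expression matrix; NaN cells become ``NA``."""
    sep = _detect_delimiter(path, delimiter)
    validate_expression(df).to_csv(path, sep=sep, na_rep="NA", float_format="%.15g")


def _parse_member(token: str) -> tuple[str, Optional[float]]:
    if "|" in token:
        fid, _, w = token.rpartition("|")
        try:
            return fid, float(w)
        except ValueError:
            pass  # a literal '|' in the id, no weight
    return token, None


def read_gmt(path: PathLike) -> list[Signature]:
    """Parse a GMT file into a list of signatures.

    Duplicate members within a line are collapsed to their first occurrence
    with a warning; the description field is discarded.  Members may use the
    ``id|weight`` extension.
    """
    signatures: list[Signature] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected name, description and >=1 member, "
                    f"got {len(fields)} fields"
                )
            name = fields[0]
            features: list[str] = []
            weights: list[float] = []
            seen: set[str] = set()
            any_weight = False
            dups: list[str] = []
            for token in fields[2:]:
                if token == "":
                    continue
                fid, w = _parse_member(token)
                if fid in seen:
                    dups.append(fid)
                    continue
                seen.add(fid)
                features.append(fid)
                weights.append(1.0 if w is None else w)
                if w is not None:
                    any_weight = True
            if dups:
                warnings.warn(
                    f"{path}: line {lineno}: signature {name!r} lists duplicate "
                    f"features {sorted(set(dups))}; keeping first occurrences"
                )
            if not features:
                raise ValueError(f"{path}: line {lineno}: signature {name!r} has no members")
            signatures.append(
                Signature(
                    name=name,
                    features=tuple(features),
                    weights=tuple(weights) if any_weight else None,
                )
            )
    return signatures


def write_gmt(signatures: Iterable[Signature], path: PathLike, description: str = "") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for sig in signatures:
            if sig.weights is None:
                members = list(sig.features)
            else:
                members = [
                    f if w == 1.0 else f"{f}|{w:.15g}"
                    for f, w in zip(sig.features, sig.weights)
                ]
            fh.write("\t".join([sig.name, description, *members]) + "\n")


def write_scores(table: pd.DataFrame, path: PathLike) -> None:
    """Write a long-format score table as TSV.

    Rows are ordered (signature, scorer, sample) lexicographically for
    deterministic output; missing scores become ``NA``.
    """
    out = table.loc[:, list(SCORE_TABLE_COLUMNS)].copy()
    out = out.sort_values(
        ["signature", "scorer", "sample_id"], kind="mergesort"
    ).reset_index(drop=True)
    out.to_csv(
        path,
        sep="\t",
        index=False,
        na_rep="NA",
        float_format="%.15g",
        quoting=csv.QUOTE_NONE,
    )


def read_scores(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={c: str for c in SCORE_TABLE_COLUMNS[:4]},
        na_values=["NA"],
        keep_default_na=False,
    )
    missing = set(SCORE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: score table missing columns {sorted(missing)}")
    df["score"] = pd.to_numeric(df["score"], errors="raise")
    df["n_features_used"] = pd.to_numeric(df["n_features_used"], errors="raise").astype(int)
    return df.loc[:, list(SCORE_TABLE_COLUMNS)]
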