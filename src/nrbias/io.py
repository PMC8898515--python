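"""Delimited-text I/O for frames, assignments and response tables.

All tables are comma-delimited with a header row. Missing self-reports
are encoded with an explicit sentinel (default ``"NA"``); round trips
through :func:`write_table`/the readers are lossless, including the
sentinel. Schema violations are reported by column name.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .factorial_design import FACTOR_LEVELS
from .synthetic_cohort import CORRELATES, OUTCOMES

NA_SENTINEL = "NA"


class SchemaError(ValueError):
    """A table is missing columns or holds out-of-domain values."""


def write_table(df: pd.DataFrame, path: str | Path, na: str = NA_SENTINEL) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep=na)
    return path


def _require(df: pd.DataFrame, columns: tuple[str, ...], what: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{what} table is missing column {col!r}")


def _check_binary(df: pd.DataFrame, col: str, what: str, allow_na: bool = False) -> None:
    values = df[col].dropna() if allow_na else df[col]
    if values.isna().any() or not values.isin([0, 1]).all():
        raise SchemaError(f"{what} column {col!r} must be binary 0/1")


def read_frame(path: str | Path, na: str = NA_SENTINEL) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[na], keep_default_na=False)
    _require(df, ("subject_id", "block", *CORRELATES), "frame")
    for c in CORRELATES:
        _check_binary(df, c, "frame")
        df[c] = df[c].astype(int)
    if df["subject_id"].duplicated().any():
        raise SchemaError("frame column 'subject_id' has duplicates")
    return df


def read_assignment(path: str | Path, na: str = NA_SENTINEL) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[na], keep_default_na=False)
    _require(df, ("subject_id", "block", "content", "source", "incentive"), "assignment")
    for factor, levels in FACTOR_LEVELS.items():
        bad = set(df[factor].unique()) - set(levels)
        if bad:
            raise SchemaError(
                f"assignment column {factor!r} has unknown levels {sorted(bad)}"
            )
    return df


def read_responses(path: str | Path, na: str = NA_SENTINEL) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[na], keep_default_na=False)
    _require(df, ("subject_id", "returned"), "responses")
    _check_binary(df, "returned", "responses")
    df["returned"] = df["returned"].astype(int)
    for col in df.columns:
        if col in ("subject_id", "returned"):
            continue
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise SchemaError(
                f"responses column {col!r} holds non-numeric values; only the "
                f"sentinel {na!r} marks missing self-reports"
            )
        _check_binary(df, col, "responses", allow_na=True)
        if (df[col].notna() & (df["returned"] == 0)).any():
            raise SchemaError(
                f"responses column {col!r} has observed values for non-returners"
            )
        df[col] = df[col].astype(float)
    return df
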