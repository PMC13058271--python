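"""Delimited-text readers/writers for the assessment and person-period tables.

Files are plain UTF-8 CSV with a header row; provenance is carried in
``#``-prefixed comment lines before the header. Writing is byte-stable for
a given table (fixed column order, fixed float format), which is what the
pipeline's determinism contract relies on.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .simulate import ASSESSMENT_COLUMNS, HOME_COLUMNS, TRUTH_COLUMNS

FLOAT_FORMAT = "%.10g"

_INT_COLS = {
    "period_index",
    "sex_female",
    "adl_hierarchy",
    "cps",
    "chess",
    "comorbidity_burden",
    "weight_change_flag",
    "fell_30d",
    "transfer",
    "died_in_period",
    "discharged_in_period",
    "acute_illness",
    "n_residents_prior_year",
    "n_transferred_prior_year",
    "start_day",
    "stop_day",
    "exposed",
    "event",
    "prev_exposed",
    "cum_exposed_prior",
    "baseline_adl",
    "baseline_cps",
    "baseline_chess",
}

_SCALE_RANGES = {
    "adl_hierarchy": (0, 6),
    "cps": (0, 6),
    "chess": (0, 5),
}


class SchemaError(ValueError):
    """Raised when a table does not conform to its documented schema."""


def write_table(
    df: pd.DataFrame, path: str, header_comments: list[str] | None = None
) -> None:
    """Write a table as CSV, optionally preceded by ``#`` comment lines."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_table(path: str, required: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, restoring integer dtypes."""
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:  # pandas reports the offending line
        raise SchemaError(f"malformed row in {path}: {exc}") from exc
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path} is missing required columns: {missing}")
        extra = [c for c in df.columns if c not in required]
        if extra:
            warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)
            df = df[required]
    for col in df.columns:
        if col in _INT_COLS and len(df):
            if not np.allclose(df[col] % 1, 0, equal_nan=False):
                raise SchemaError(f"{path}: column {col!r} must be integer-valued")
            df[col] = df[col].astype(np.int64)
        elif col in _INT_COLS:
            df[col] = df[col].astype(np.int64)
    return df


def validate_assessments(df: pd.DataFrame) -> None:
    """Check scale ranges and per-resident structural invariants."""
    for col, (lo, hi) in _SCALE_RANGES.items():
        bad = df[(df[col] < lo) | (df[col] > hi)]
        if len(bad):
            ids = sorted(bad["resident_id"].unique())[:5]
            raise SchemaError(
                f"{col} outside [{lo}, {hi}] for residents {ids}"
            )
    first = df.groupby("resident_id")["period_index"].min()
    missing0 = first[first != 0]
    if len(missing0):
        raise SchemaError(
            f"residents missing an admission (period-0) row: {sorted(missing0.index)[:5]}"
        )
    g = df.groupby("resident_id")["period_index"]
    n_rows, pmax = g.size(), g.max()
    noncontig = n_rows[n_rows != pmax + 1]
    if len(noncontig):
        raise SchemaError(
            f"non-contiguous period indices for residents {sorted(noncontig.index)[:5]}"
        )


def write_cohort(df: pd.DataFrame, path: str, header_comments: list[str] | None = None) -> None:
    missing = [c for c in ASSESSMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"assessment table missing columns: {missing}")
    write_table(df[ASSESSMENT_COLUMNS], path, header_comments)


def read_cohort(path: str) -> pd.DataFrame:
    df = read_table(path, required=ASSESSMENT_COLUMNS)
    if len(df):
        validate_assessments(df)
    return df


def write_truth(truth_table: pd.DataFrame, path: str, header_comments=None) -> None:
    write_table(truth_table[TRUTH_COLUMNS], path, header_comments)


def write_home_history(df: pd.DataFrame, path: str, header_comments=None) -> None:
    write_table(df[HOME_COLUMNS], path, header_comments)


def read_home_history(path: str) -> pd.DataFrame:
    return read_table(path, required=HOME_COLUMNS)
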