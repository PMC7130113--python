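"""CSV interchange for trial records and subject metadata.

One dialect everywhere: comma-separated, UTF-8, header row, "." decimal
separator, missing values as empty fields.  Readers validate records and
report malformed rows with their line numbers; SOA values outside the
standard set are warned about but retained, while structurally invalid rows
(SOA of 0, bad labels, duplicate trial keys) are errors.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .design import POSTURES, SOA_LEVELS_MS
from .observer import GROUPS, RESPONSES, SIDES

TRIAL_COLUMNS = ["subject_id", "block", "trial_index", "posture", "soa_ms", "response"]
META_COLUMNS = [
    "subject_id",
    "group",
    "affected_side",
    "pain_duration_months",
    "pain_intensity",
    "temp_diff_c",
    "temp_imputed",
]


class ValidationError(ValueError):
    """Raised when an input file violates the trial/metadata contracts."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def _bad_rows(df: pd.DataFrame, mask, path, what: str) -> None:
    # +2: header line plus 1-based indexing
    if mask.any():
        lines = (df.index[mask] + 2).tolist()
        raise ValidationError(f"{path}: {what} at lines {lines[:20]}")


def read_trials(path) -> pd.DataFrame:
    """Read and validate a tidy trial CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, TRIAL_COLUMNS, path)
    df = df[TRIAL_COLUMNS]
    _bad_rows(df, df["soa_ms"].isna() | (df["soa_ms"] == 0), path, "invalid SOA (0 or missing)")
    _bad_rows(df, ~df["posture"].isin(POSTURES), path, "unknown posture label")
    _bad_rows(df, ~df["response"].isin(RESPONSES), path, "unknown response label")
    dup = df.duplicated(subset=["subject_id", "block", "trial_index"], keep=False)
    _bad_rows(df, dup, path, "duplicate subject x block x trial key")
    nonstd = ~df["soa_ms"].isin(SOA_LEVELS_MS)
    if nonstd.any():
        warnings.warn(
            f"{path}: {int(nonstd.sum())} trials with SOA outside the standard "
            f"set {SOA_LEVELS_MS}; retained",
            stacklevel=2,
        )
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_meta(path) -> pd.DataFrame:
    """Read and validate a subject-metadata CSV (missing temp_diff_c = empty)."""
    path = Path(path)
    df = pd.read_csv(path)
    if "temp_imputed" not in df.columns:
        df["temp_imputed"] = False
    _require_columns(df, META_COLUMNS, path)
    df = df[META_COLUMNS]
    _bad_rows(df, ~df["group"].isin(GROUPS), path, "unknown group label")
    _bad_rows(df, ~df["affected_side"].isin(SIDES), path, "unknown affected_side")
    _bad_rows(df, df["pain_duration_months"] < 0, path, "negative pain duration")
    _bad_rows(
        df,
        ~df["pain_intensity"].between(0, 10),
        path,
        "pain_intensity outside [0, 10]",
    )
    _bad_rows(df, df["subject_id"].duplicated(keep=False), path, "duplicate subject_id")
    df["temp_imputed"] = df["temp_imputed"].astype(bool)
    return df


def write_meta(meta: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    meta[META_COLUMNS].to_csv(path, index=False)
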