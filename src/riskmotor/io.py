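"""Trial-table CSV reading/writing with schema validation.

Dialect: comma-separated, UTF-8, '.' decimal, header row required.  A
missing observation (no-feedback trial) is an empty field.  Provenance
(config hash, seed) is written as leading ``# key=value`` comment lines,
which readers skip.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError
from .model import FEEDBACK_LABELS, FORCE_LABELS
from .simulate import TRIAL_COLUMNS

__all__ = ["read_trials", "write_trials", "write_table"]

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


def write_table(
    df: pd.DataFrame, path, provenance: Mapping[str, object] | None = None
) -> None:
    """Write any result table as CSV with optional provenance comments."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def write_trials(
    trials: pd.DataFrame, path, provenance: Mapping[str, object] | None = None
) -> None:
    """Write a trial table; observation_x NaN becomes an empty field."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing column(s): {missing}")
    write_table(trials[list(TRIAL_COLUMNS)], path, provenance)


def read_trials(path, halfwidth: float | None = None) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Checks the exact column set, numeric fields, label values, the rule
    that observation_x is absent iff feedback_label == NONE, and — when
    ``halfwidth`` is given — that the hit flag matches
    |response - target| <= halfwidth.  Errors name the offending data row
    (1-based, excluding header/comments).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, comment="#", dtype={"subject_id": str})
    if list(df.columns) != list(TRIAL_COLUMNS):
        raise SchemaError(
            f"columns {list(df.columns)} do not match required {list(TRIAL_COLUMNS)}"
        )
    if len(df) == 0:
        return df

    def _bad_row(mask: pd.Series, message: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0]) + 1
            raise SchemaError(f"row {row}: {message}")

    for col in ("block_index", "trial_index"):
        vals = pd.to_numeric(df[col], errors="coerce")
        _bad_row(vals.isna() | (vals != vals.round()), f"{col} must be an integer")
        df[col] = vals.astype(int)
    for col in ("target_x", "observation_x", "response_x"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if col != "observation_x":
            _bad_row(vals.isna(), f"{col} must be numeric")
        else:
            _bad_row(vals.isna() & df[col].notna(), f"{col} must be numeric or empty")
        df[col] = vals
    _bad_row(~df["force_label"].isin(FORCE_LABELS), "unknown force_label")
    _bad_row(~df["feedback_label"].isin(FEEDBACK_LABELS), "unknown feedback_label")

    none_mask = df["feedback_label"] == "NONE"
    _bad_row(none_mask & df["observation_x"].notna(),
             "observation recorded on a NONE (no-feedback) trial")
    _bad_row(~none_mask & df["observation_x"].isna(),
             "observation missing on a trial with feedback")

    if df["hit"].dtype != bool:
        hit = df["hit"].astype(str).str.strip().str.lower().map(_BOOL_MAP)
        _bad_row(hit.isna(), "hit must be a boolean")
        df["hit"] = hit.astype(bool)
    if halfwidth is not None:
        expected = (df["response_x"] - df["target_x"]).abs() <= halfwidth
        _bad_row(df["hit"] != expected,
                 f"hit flag inconsistent with halfwidth={halfwidth}")
    return df
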