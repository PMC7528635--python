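"""Cohort table I/O with schema validation.

CSV schema (comma-separated, UTF-8, header required):
``child_id, age, gender, dow, tod, z_attention, z_timeliness,
z_hyperactivity, z_impulsiveness, diagnosis``
with age an integer in 6..12, gender coded 0 (boy) / 1 (girl), dow 1..7,
tod 1..3 and diagnosis in {ADHD, control}.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import AGE_LEVELS, DOW_LEVELS, GENDER_LEVELS, INDEX_COLUMNS, TOD_LEVELS

__all__ = ["COHORT_COLUMNS", "read_cohort_csv", "write_cohort_csv"]

COHORT_COLUMNS = ("child_id", "age", "gender", "dow", "tod", *INDEX_COLUMNS, "diagnosis")

_LEVELS = {"age": AGE_LEVELS, "gender": GENDER_LEVELS, "dow": DOW_LEVELS, "tod": TOD_LEVELS}


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort table; errors cite offending rows."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col, levels in _LEVELS.items():
        bad = ~df[col].isin(levels)
        if bad.any():
            rows = (df.index[bad] + 2).tolist()  # 1-based incl. header
            raise ValueError(f"{path}: invalid {col} values at rows {rows}")
    bad = ~df["diagnosis"].isin(["ADHD", "control"])
    if bad.any():
        rows = (df.index[bad] + 2).tolist()
        raise ValueError(f"{path}: invalid diagnosis labels at rows {rows}")
    z = df[list(INDEX_COLUMNS)].to_numpy(dtype=float)
    if not np.isfinite(z).all():
        raise ValueError(f"{path}: non-finite index z-scores")
    if df["child_id"].duplicated().any():
        dup = df.loc[df["child_id"].duplicated(), "child_id"].tolist()
        raise ValueError(f"{path}: duplicate child_id values {dup}")
    return df[list(COHORT_COLUMNS)]


def write_cohort_csv(records: pd.DataFrame, path: str | Path) -> None:
    records[list(COHORT_COLUMNS)].to_csv(path, index=False)
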