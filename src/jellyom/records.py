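"""Tidy time-series records and CSV I/O shared by all analysis stages.

The on-disk schema is one row per measurement:

    experiment, replicate, treatment, time_h, analyte, value, unit
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

TIDY_COLUMNS = ["experiment", "replicate", "treatment", "time_h", "analyte", "value", "unit"]


@dataclass(frozen=True)
class TimeSeriesRecord:
    """A single measurement in a flask at one timepoint."""

    experiment: str
    replicate: str
    treatment: str
    time_h: float
    analyte: str
    value: float
    unit: str


class UnitMismatchError(ValueError):
    """Raised when a series mixes units for one analyte."""


def to_frame(records: list[TimeSeriesRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=TIDY_COLUMNS)


def read_tidy_csv(path: str | Path) -> pd.DataFrame:
    """Read a tidy measurement CSV, validating the schema."""
    df = pd.read_csv(path)
    missing = [c for c in TIDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tidy CSV {path} missing columns: {missing}")
    df["time_h"] = df["time_h"].astype(float)
    df["value"] = df["value"].astype(float)
    return df[TIDY_COLUMNS]


def write_tidy_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[TIDY_COLUMNS].to_csv(path, index=False)


def select(
    df: pd.DataFrame,
    analyte: str | None = None,
    treatment: str | None = None,
    experiment: str | None = None,
    replicate: str | None = None,
) -> pd.DataFrame:
    """Filter a tidy frame; only non-None keys constrain."""
    mask = pd.Series(True, index=df.index)
    for col, val in (
        ("analyte", analyte),
        ("treatment", treatment),
        ("experiment", experiment),
        ("replicate", replicate),
    ):
        if val is not None:
            mask &= df[col] == val
    return df[mask]


def single_unit(df: pd.DataFrame) -> str:
    """Return the single unit of a series, rejecting mixtures."""
    units = df["unit"].unique()
    if len(units) != 1:
        raise UnitMismatchError(f"mixed units in series: {sorted(units)}")
    return str(units[0])


def series_arrays(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Time-sorted (times, values) arrays for a single-replicate series."""
    sub = df.sort_values("time_h")
    return sub["time_h"].to_numpy(float), sub["value"].to_numpy(float)
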