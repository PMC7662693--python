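"""Amino-acid and nutrient pool bookkeeping.

Tracks the total hydrolyzable (TDHAA), free (DFAA) and combined
(DCAA = TDHAA - DFAA) amino-acid pools, per-species mol%, and signed net
consumption / accumulation rates over growth phases. Sign convention:
negative = net consumption, positive = net accumulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _fit, records

#: Canonical pooling of chromatographically co-eluting species. Editable.
CANONICAL_SPECIES: dict[str, str] = {
    "Glu": "Glx",
    "Gln": "Glx",
    "Asp": "Asx",
    "Asn": "Asx",
}

PHASE_LABELS = ("exponential", "stationary", "senescent")


class NegativePoolWarning(UserWarning):
    """A derived pool came out negative (measurement noise)."""


@dataclass(frozen=True)
class PhaseWindow:
    """One labelled growth phase; windows must not overlap."""

    label: str
    t_start_h: float
    t_end_h: float

    def __post_init__(self) -> None:
        if self.label not in PHASE_LABELS:
            raise ValueError(f"label must be one of {PHASE_LABELS}")
        if not self.t_end_h > self.t_start_h:
            raise ValueError("t_end_h must exceed t_start_h")


@dataclass
class NetRate:
    """Signed net rate of one analyte over one phase (units per hour)."""

    analyte: str
    phase: str
    rate: float
    sd: float
    n_replicates: int = 1
    below_floor: bool = False
    flags: list[str] = field(default_factory=list)


def default_phases(peak_h: float = 32.0, stationary_end_h: float = 46.0,
                   end_h: float = 84.0) -> list[PhaseWindow]:
    """Exponential up to the abundance peak, stationary to ~46 h, then senescent."""
    return [
        PhaseWindow("exponential", 0.0, peak_h),
        PhaseWindow("stationary", peak_h, stationary_end_h),
        PhaseWindow("senescent", stationary_end_h, end_h),
    ]


def canonicalize(species: str, table: dict[str, str] | None = None) -> str:
    table = CANONICAL_SPECIES if table is None else table
    return table.get(species, species)


def dcaa(thdaa: float, dfaa: float) -> float:
    """Combined amino acids as the difference of the total and free pools.

    A negative result (noise) is returned unchanged with a warning.
    """
    out = thdaa - dfaa
    if out < 0:
        warnings.warn(
            f"DCAA = TDHAA - DFAA is negative ({out}): measurement noise?",
            NegativePoolWarning,
            stacklevel=2,
        )
    return out


def mol_percent(profile: dict[str, float]) -> dict[str, float]:
    """Per-species molar percentages of a pool; shares sum to 100.

    Negative concentrations are excluded (with a warning) before
    normalizing; an all-zero/empty profile is rejected.
    """
    clean = {}
    for sp, conc in profile.items():
        if conc < 0:
            warnings.warn(
                f"excluding negative concentration for {sp}", NegativePoolWarning,
                stacklevel=2,
            )
            continue
        clean[canonicalize(sp)] = clean.get(canonicalize(sp), 0.0) + conc
    total = sum(clean.values())
    if total <= 0:
        raise ValueError("profile has no positive concentrations")
    return {sp: 100.0 * c / total for sp, c in clean.items()}


def net_rate(
    series: pd.DataFrame,
    phase: PhaseWindow,
    method: str = "ols",
    floor: float | None = None,
) -> NetRate:
    """Signed net rate of one analyte within a phase window.

    Slope per replicate (OLS default, endpoint optional) over points with
    ``t_start_h <= t <= t_end_h``, then mean ± SD across replicates. Rates
    with |rate| below ``floor`` are flagged ``below_floor``.
    """
    analytes = series["analyte"].unique()
    if len(analytes) != 1:
        raise ValueError(f"series must hold a single analyte, got {sorted(analytes)}")
    records.single_unit(series)

    slopes = []
    for _, sub in series.groupby("replicate"):
        t, y = records.series_arrays(sub)
        mask = (t >= phase.t_start_h - 1e-9) & (t <= phase.t_end_h + 1e-9)
        if mask.sum() < 2:
            raise ValueError(
                f"replicate has <2 points inside phase {phase.label!r}"
            )
        slopes.append(_fit.fit_slope(t[mask], y[mask], method))

    arr = np.asarray(slopes)
    rate = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return NetRate(
        analyte=str(analytes[0]),
        phase=phase.label,
        rate=rate,
        sd=sd,
        n_replicates=int(arr.size),
        below_floor=bool(floor is not None and abs(rate) < floor),
    )


def pool_fraction_remaining(initial_pool: float, current_pool: float) -> float:
    """Percentage of the initial pool still present."""
    if initial_pool <= 0:
        raise ValueError("initial pool must be > 0")
    return 100.0 * current_pool / initial_pool


def doc_don_ratio(
    doc_series: pd.DataFrame, don_series: pd.DataFrame, timepoint: float
) -> float:
    """Molar DOC:DON ratio at one timepoint (means across replicates)."""
    doc = doc_series[np.isclose(doc_series["time_h"], timepoint)]["value"]
    don = don_series[np.isclose(don_series["time_h"], timepoint)]["value"]
    if doc.empty or don.empty:
        raise ValueError(f"both series must have values at t={timepoint}")
    don_mean = float(don.mean())
    if don_mean == 0:
        raise ZeroDivisionError("DON is zero at the requested timepoint")
    return float(doc.mean()) / don_mean


def net_rate_table(
    df: pd.DataFrame,
    phases: list[PhaseWindow],
    analytes: list[str],
    method: str = "ols",
    floor: float | None = None,
) -> pd.DataFrame:
    """NetRate rows for every (analyte, phase) pair with enough data."""
    check_phases(phases)
    rows = []
    for analyte in analytes:
        sub = records.select(df, analyte=analyte)
        if sub.empty:
            continue
        for phase in phases:
            try:
                nr = net_rate(sub, phase, method=method, floor=floor)
            except ValueError:
                continue
            rows.append(
                {
                    "analyte": nr.analyte,
                    "phase": nr.phase,
                    "rate_per_h": nr.rate,
                    "sd": nr.sd,
                    "n_replicates": nr.n_replicates,
                    "below_floor": nr.below_floor,
                    "method": method,
                }
            )
    return pd.DataFrame(rows)


def check_phases(phases: list[PhaseWindow]) -> None:
    """Reject overlapping or out-of-order phase windows."""
    ordered = sorted(phases, key=lambda p: p.t_start_h)
    for a, b in zip(ordered, ordered[1:]):
        if b.t_start_h < a.t_end_h - 1e-9:
            raise ValueError(f"phases {a.label!r} and {b.label!r} overlap")
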