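"""Dry-mass-normalized release rates from leaching experiments.

Converts concentration time series measured on a known mass of freeze-dried
detrital material suspended in a known volume into per-mg-dry-mass daily
release rates, partitions the dissolved pools, and projects the enrichment
expected from a decaying bloom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _fit, records, stoichiometry

#: Element carried by each analyte, for the dual μmol/μg rate table.
ANALYTE_ELEMENT: dict[str, str] = {
    "POC": "C",
    "DOC": "C",
    "TOC": "C",
    "PN": "N",
    "TDN": "N",
    "DON": "N",
    "DIN": "N",
    "NH4": "N",
    "NO3": "N",
    "NO2": "N",
    "PO4": "P",
}


@dataclass(frozen=True)
class LeachingSetup:
    """Mass/volume/duration of one leaching flask."""

    dm_mass_mg: float = 250.0
    volume_l: float = 1.0
    duration_h: float = 24.0
    replicate_id: str = "F1"

    def __post_init__(self) -> None:
        for name in ("dm_mass_mg", "volume_l", "duration_h"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ReleaseRate:
    """Per-analyte release rate in μmol (mg DM)^-1 d^-1 with uncertainty."""

    analyte: str
    rate_umol_per_mg_per_d: float
    sd: float = 0.0
    n_replicates: int = 1
    method: str = "ols"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.rate_umol_per_mg_per_d < 0 and "negative_rate" not in self.flags:
            self.flags.append("negative_rate")

    @property
    def rate_ug_per_mg_per_d(self) -> float | None:
        """Mass-based rate, when the analyte maps to a single element."""
        element = ANALYTE_ELEMENT.get(self.analyte)
        if element is None:
            return None
        return stoichiometry.umol_to_ug(self.rate_umol_per_mg_per_d, element)


@dataclass(frozen=True)
class BloomScenario:
    """Standing stock of decaying individuals feeding the water column."""

    individuals_per_m3: float = 10.0
    dm_per_individual_g: float = 10.0
    c_wt_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.individuals_per_m3 < 0:
            raise ValueError("individuals_per_m3 must be >= 0")
        for name in ("dm_per_individual_g", "c_wt_fraction"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def release_rate(
    series: pd.DataFrame,
    setup: LeachingSetup,
    method: str = "ols",
    pre_plateau: bool = False,
) -> ReleaseRate:
    """Release rate of one analyte from a tidy concentration series.

    Parameters
    ----------
    series : DataFrame
        Tidy rows for a single analyte (μmol L^-1), one or more replicates.
    setup : LeachingSetup
        Mass and volume of material leached.
    method : {"ols", "endpoint"}
        Slope estimator applied per replicate; hourly slopes are scaled by
        24 to daily rates.
    pre_plateau : bool
        If True, restrict the OLS fit per replicate to the contiguous
        prefix of >= 3 points maximizing R^2 (saturating series).

    Returns
    -------
    ReleaseRate
        Replicate rates averaged, SD across replicates (0 for a single
        replicate).
    """
    analytes = series["analyte"].unique()
    if len(analytes) != 1:
        raise ValueError(f"series must hold a single analyte, got {sorted(analytes)}")
    records.single_unit(series)

    rates = []
    for _, sub in series.groupby("replicate"):
        t, y = records.series_arrays(sub)
        if t.size < 2:
            raise ValueError("each replicate needs >= 2 timepoints")
        if pre_plateau and method == "ols" and t.size >= 3:
            slope_h, _ = _fit.best_prefix_slope(t, y)
        else:
            slope_h = _fit.fit_slope(t, y, method)
        rates.append(slope_h * 24.0 * setup.volume_l / setup.dm_mass_mg)

    rates_arr = np.asarray(rates)
    sd = float(np.std(rates_arr, ddof=1)) if rates_arr.size > 1 else 0.0
    return ReleaseRate(
        analyte=str(analytes[0]),
        rate_umol_per_mg_per_d=float(np.mean(rates_arr)),
        sd=sd,
        n_replicates=int(rates_arr.size),
        method=method,
    )


def toc_rate(poc: ReleaseRate, doc: ReleaseRate) -> ReleaseRate:
    """Total organic carbon rate: POC + DOC, SDs combined in quadrature."""
    if poc.analyte != "POC" or doc.analyte != "DOC":
        raise ValueError(
            f"expected (POC, DOC) rates, got ({poc.analyte}, {doc.analyte})"
        )
    return ReleaseRate(
        analyte="TOC",
        rate_umol_per_mg_per_d=poc.rate_umol_per_mg_per_d + doc.rate_umol_per_mg_per_d,
        sd=math.hypot(poc.sd, doc.sd),
        n_replicates=min(poc.n_replicates, doc.n_replicates),
        method=poc.method,
    )


def toc_percent_of_dm(toc: ReleaseRate) -> float:
    """Daily TOC release as a percentage of the dry mass leached.

    μmol mg^-1 d^-1 -> μg mg^-1 d^-1 via the atomic mass of carbon, then
    divided by the 1000 μg in each mg and expressed as %.
    """
    pct = stoichiometry.umol_to_ug(toc.rate_umol_per_mg_per_d, "C") / 1000.0 * 100.0
    if pct < 0:
        toc.flags.append("negative_toc_percent")
    return pct


def din_partition(
    nh4: ReleaseRate, no3: ReleaseRate, no2: ReleaseRate
) -> dict[str, float | dict[str, float]]:
    """Sum the inorganic nitrogen species and report each species' share.

    Returns ``{"din_total": rate, "shares_pct": {analyte: %}}`` with shares
    summing to 100.
    """
    species = {r.analyte: r.rate_umol_per_mg_per_d for r in (nh4, no3, no2)}
    if any(v < 0 for v in species.values()):
        raise ValueError("DIN species rates must be >= 0")
    total = sum(species.values())
    if total == 0:
        raise ZeroDivisionError("all DIN species are zero: shares undefined")
    return {
        "din_total": total,
        "shares_pct": {k: 100.0 * v / total for k, v in species.items()},
    }


def lmw_fraction(dialyzate_pool: float, total_pool: float) -> float:
    """Percentage of a pool below the dialysis cut-off (~1000 Da)."""
    if total_pool <= 0:
        raise ValueError("total pool must be > 0")
    return 100.0 * dialyzate_pool / total_pool


def predict_enrichment(rate: ReleaseRate, amendment_mg_per_l: float) -> float:
    """Concentration (μmol L^-1) released per day by a dry-mass amendment."""
    if amendment_mg_per_l <= 0:
        raise ValueError("amendment must be > 0 mg L^-1")
    return rate.rate_umol_per_mg_per_d * amendment_mg_per_l


def bloom_load(scenario: BloomScenario) -> dict[str, float]:
    """Dry mass and organic carbon delivered per m^3 by a decaying bloom."""
    dm = scenario.individuals_per_m3 * scenario.dm_per_individual_g
    return {"dm_g_per_m3": dm, "c_g_per_m3": dm * scenario.c_wt_fraction}


def check_consistency(
    rates: dict[str, ReleaseRate], rel_tol: float = 0.15
) -> list[str]:
    """Cross-check additive identities on a rate table.

    DIN should equal NH4 + NO3 + NO2 and DON should equal TDN - DIN within
    ``rel_tol`` relative tolerance whenever the constituents are present.
    Returns a list of violation messages (empty when consistent).
    """
    problems: list[str] = []

    def val(name: str) -> float | None:
        r = rates.get(name)
        return None if r is None else r.rate_umol_per_mg_per_d

    din, nh4, no3, no2 = (val(a) for a in ("DIN", "NH4", "NO3", "NO2"))
    if None not in (din, nh4, no3, no2):
        expected = nh4 + no3 + no2
        if not math.isclose(din, expected, rel_tol=rel_tol, abs_tol=1e-12):
            problems.append(f"DIN {din} != NH4+NO3+NO2 {expected}")
    tdn, don = val("TDN"), val("DON")
    if None not in (tdn, don, din):
        expected = tdn - din
        if not math.isclose(don, expected, rel_tol=rel_tol, abs_tol=1e-12):
            problems.append(f"DON {don} != TDN-DIN {expected}")
    return problems


def rate_table(rates: dict[str, ReleaseRate]) -> pd.DataFrame:
    """Dual-unit (μmol and μg per mg per day) release-rate table."""
    rows = []
    for name, r in rates.items():
        rows.append(
            {
                "analyte": name,
                "rate_umol_per_mg_per_d": r.rate_umol_per_mg_per_d,
                "sd_umol": r.sd,
                "rate_ug_per_mg_per_d": r.rate_ug_per_mg_per_d,
                "n_replicates": r.n_replicates,
                "method": r.method,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)
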