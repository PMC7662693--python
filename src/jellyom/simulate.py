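"""Synthetic data with known ground truth for parameter-recovery tests.

Four generators mirror the four input families of the analysis:

* first-order leaching toward a 24-h plateau,
* multi-analyte batch cultures (exponential growth coupled to substrate
  drawdown through a prescribed growth efficiency),
* per-protein exponentially decaying PSM tables,
* multinomial read counts over features of unequal length.

All noise flows from a single ``numpy`` Generator seeded by
``SimParams.seed``, so outputs are deterministic given the seed. At zero
noise every downstream estimator recovers its programmed parameter
exactly: growth is coupled to carbon through the budget identity
BCD = BP / BGE rather than a mechanistic substrate model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .abundance import FeatureCount
from .proteome import PSMRecord
from .records import TIDY_COLUMNS
from .stoichiometry import ATOMIC_MASS

#: Default subsampling grids (hours).
LEACHING_GRID = (0.0, 0.5, 1.0, 2.0, 6.0, 8.0, 12.0, 24.0)
BATCH_GRID_SHORT = (0.0, 6.0, 12.0, 24.0, 32.0)
BATCH_GRID_LONG = (0.0, 12.0, 32.0, 46.0, 56.0, 80.0, 84.0)


@dataclass
class SimParams:
    """Ground-truth parameters for all generators."""

    seed: int = 0
    # growth
    mu_per_h: float = 0.09
    n0_cells_per_ml: float = 5.7e5
    peak_time_h: float = 32.0
    decay_rate_per_h: float = 0.02
    mu_control_per_h: float = 0.02
    # carbon
    bge: float = 0.65
    fg_c_per_cell: float = 19.8
    doc0_umol_l: float = 44.0
    doc_background_umol_l: float = 25.0
    # amino acids / nutrients
    thdaa0_umol_l: float = 11.0
    dfaa_fraction: float = 0.55
    dfaa_k_per_h: float = 0.12
    dcaa_k_per_h: float = 0.10
    dfaa_switch_fraction: float = 0.03
    nh4_slope_umol_l_h: float = 0.29
    po4_slope_umol_l_h: float = 0.016
    tdn0_umol_l: float = 15.9
    tdn_slope_umol_l_h: float = 0.58
    leucine_peak_umol_l: float = 3.9
    tryptophan_slope_nmol_l_h: float = 3.8
    tryptophan_onset_h: float = 46.0
    # leaching
    leach_k_per_h: float = 0.15
    plateau_umol_l: dict = field(
        default_factory=lambda: {"DOC": 110.0, "TDN": 32.5, "POC": 105.0, "PN": 30.0}
    )
    # noise: one CV for everything, or a per-analyte mapping with a
    # "default" fallback key
    noise_cv: float | dict = 0.05
    # design
    n_replicates: int = 3
    grid: tuple = BATCH_GRID_SHORT
    # proteome
    protein_decay_per_h: dict = field(
        default_factory=lambda: {
            "P_nrps": 0.105,
            "P_ubiquitin": 0.12,
            "P_fibrillin": 0.16,
            "P_collagen": 0.16,
            "P_myosin": 0.20,
            "P_actin": 0.075,
            "P_titin": 0.08,
        }
    )
    protein_initial_weights: dict = field(
        default_factory=lambda: {
            "P_nrps": 10.0,
            "P_ubiquitin": 8.0,
            "P_fibrillin": 25.0,
            "P_collagen": 12.0,
            "P_myosin": 22.0,
            "P_actin": 10.0,
            "P_titin": 6.0,
        }
    )
    psm_pool0: float = 203.45
    # community
    mag_profile: dict = field(
        default_factory=lambda: {
            "MAG_alteromonas": 0.43,
            "MAG_pseudoalteromonas": 0.39,
            "MAG_vibrio": 0.07,
            "MAG_other": 0.11,
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.bge <= 1.5:
            raise ValueError("bge must lie in (0, 1.5]")
        if not 0.0 <= self.dfaa_fraction <= 1.0:
            raise ValueError("dfaa_fraction must lie in [0, 1]")
        for name in ("mu_per_h", "leach_k_per_h", "dfaa_k_per_h", "dcaa_k_per_h",
                     "decay_rate_per_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        cvs = (
            self.noise_cv.values() if isinstance(self.noise_cv, dict) else [self.noise_cv]
        )
        if any(cv < 0 for cv in cvs):
            raise ValueError("noise_cv must be >= 0")

    def cv_for(self, analyte: str) -> float:
        """Noise CV for one analyte (mapping lookup or the scalar)."""
        if isinstance(self.noise_cv, dict):
            return float(self.noise_cv.get(analyte, self.noise_cv.get("default", 0.0)))
        return float(self.noise_cv)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def truth(self) -> dict:
        """Ground-truth sidecar (JSON-serializable)."""
        d = asdict(self)
        d["grid"] = list(self.grid)
        return d


def _lognormal_noise(rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
    """Mean-preserving multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return values
    sigma = math.sqrt(math.log1p(cv * cv))
    return values * rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=values.shape)


def _rows(experiment, replicate, treatment, times, values, analyte, unit):
    return [
        {
            "experiment": experiment,
            "replicate": replicate,
            "treatment": treatment,
            "time_h": float(t),
            "analyte": analyte,
            "value": float(v),
            "unit": unit,
        }
        for t, v in zip(times, values)
    ]


def simulate_leaching(
    params: SimParams,
    analyte_targets: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """First-order leaching series C(t) = C_plateau * (1 - e^(-k t)).

    Two flasks x two technical replicates per analyte on the standard
    0-24 h grid, with multiplicative lognormal noise.
    """
    rng = params.rng() if rng is None else rng
    targets = params.plateau_umol_l if analyte_targets is None else analyte_targets
    t = np.asarray(LEACHING_GRID)
    rows = []
    for analyte, plateau in targets.items():
        clean = plateau * (1.0 - np.exp(-params.leach_k_per_h * t))
        for flask in ("F1", "F2"):
            for tech in ("a", "b"):
                noisy = _lognormal_noise(rng, clean, params.cv_for(analyte))
                rows += _rows(
                    "leaching", f"{flask}{tech}", "leachate", t, noisy, analyte,
                    "umol L-1",
                )
    return pd.DataFrame(rows, columns=TIDY_COLUMNS)


def _cells_trajectory(params: SimParams, t: np.ndarray, mu: float) -> np.ndarray:
    """Exponential growth to the peak, then first-order decay (cells mL^-1)."""
    peak = params.n0_cells_per_ml * math.exp(mu * params.peak_time_h)
    growing = params.n0_cells_per_ml * np.exp(mu * np.minimum(t, params.peak_time_h))
    decayed = peak * np.exp(-params.decay_rate_per_h * np.maximum(t - params.peak_time_h, 0.0))
    return np.where(t <= params.peak_time_h, growing, decayed)


def simulate_batch_culture(params: SimParams) -> pd.DataFrame:
    """Multi-analyte batch-culture series for amended and control flasks.

    Carbon closes exactly at zero noise: the DOC drawdown equals the
    biomass increase divided by the programmed growth efficiency,
    DOC(t) = DOC0 - (N(t) - N0) * fgC / (BGE * M_C) in μmol C L^-1. DFAA
    decays first-order until it falls below ``dfaa_switch_fraction`` of its
    start, after which DCAA decays; NH4+ and PO4^3- accumulate linearly;
    leucine is a transient bump and tryptophan a late linear accumulation.
    """
    rng = params.rng()
    t = np.asarray(params.grid, float)
    rows: list[dict] = []

    dfaa0 = params.thdaa0_umol_l * params.dfaa_fraction
    dcaa0 = params.thdaa0_umol_l - dfaa0
    if params.dfaa_k_per_h > 0:
        t_switch = -math.log(params.dfaa_switch_fraction) / params.dfaa_k_per_h
    else:
        t_switch = math.inf

    for treatment, mu in (("jelly", params.mu_per_h), ("control", params.mu_control_per_h)):
        amended = treatment == "jelly"
        for rep in range(1, params.n_replicates + 1):
            replicate = f"{treatment[0].upper()}{rep}"
            cells = _cells_trajectory(params, t, mu)

            # DOC coupled to growth through the budget identity; frozen at
            # its minimum once cells decay (no re-release of carbon).
            n_cap = np.minimum(cells, params.n0_cells_per_ml * math.exp(mu * params.peak_time_h))
            n_eff = np.maximum.accumulate(n_cap)
            delta_biomass_ugc = (n_eff - params.n0_cells_per_ml) * 1e3 * params.fg_c_per_cell * 1e-9
            drawdown_umol = delta_biomass_ugc / (params.bge * ATOMIC_MASS["C"])
            doc0 = params.doc_background_umol_l + (params.doc0_umol_l if amended else 0.0)
            doc = doc0 - drawdown_umol

            if amended:
                dfaa = dfaa0 * np.exp(-params.dfaa_k_per_h * t)
                dcaa = np.where(
                    t < t_switch,
                    dcaa0,
                    dcaa0 * np.exp(-params.dcaa_k_per_h * (t - t_switch)),
                )
                nh4 = 0.5 + params.nh4_slope_umol_l_h * t
                po4 = 0.05 + params.po4_slope_umol_l_h * t
                tdn = params.tdn0_umol_l + params.tdn_slope_umol_l_h * t
                leu = params.leucine_peak_umol_l * (t / params.peak_time_h) * np.exp(
                    1.0 - t / params.peak_time_h
                )
                trp = (
                    params.tryptophan_slope_nmol_l_h
                    * 1e-3
                    * np.maximum(t - params.tryptophan_onset_h, 0.0)
                )
            else:
                dfaa = np.full_like(t, 0.05)
                dcaa = np.full_like(t, 0.45)
                nh4 = np.full_like(t, 0.5)
                po4 = np.full_like(t, 0.05)
                tdn = np.full_like(t, 4.0)
                leu = np.full_like(t, 0.01)
                trp = np.full_like(t, 0.005)

            don = tdn - nh4
            series = [
                ("cells", cells, "cells mL-1"),
                ("DOC", doc, "umol L-1"),
                ("TDN", tdn, "umol L-1"),
                ("DON", don, "umol L-1"),
                ("DFAA", dfaa, "umol L-1"),
                ("DCAA", dcaa, "umol L-1"),
                ("NH4", nh4, "umol L-1"),
                ("PO4", po4, "umol L-1"),
                ("leucine", leu, "umol L-1"),
                ("tryptophan", trp, "umol L-1"),
            ]
            for analyte, clean, unit in series:
                noisy = _lognormal_noise(rng, np.asarray(clean, float), params.cv_for(analyte))
                rows += _rows("batch", replicate, treatment, t, noisy, analyte, unit)

    return pd.DataFrame(rows, columns=TIDY_COLUMNS)


def simulate_psm_table(
    params: SimParams,
    timepoints: tuple[float, ...] = (0.0, 32.0, 84.0),
    poisson_noise: bool = False,
    aa_length: int = 500,
) -> list[PSMRecord]:
    """Per-protein exponentially decaying PSM table.

    Initial per-protein weights are rescaled so the 0-h pool total equals
    ``params.psm_pool0``; each protein then decays at its own rate.
    Optional Poisson noise discretizes the PSM counts.
    """
    if not params.protein_decay_per_h:
        raise ValueError("need >= 1 protein with a decay rate")
    rng = params.rng()
    weights = params.protein_initial_weights
    scale = params.psm_pool0 / sum(weights[p] for p in params.protein_decay_per_h)
    out: list[PSMRecord] = []
    for t in timepoints:
        for pid, rate in params.protein_decay_per_h.items():
            per_aa = weights[pid] * scale * math.exp(-rate * t)
            psms = per_aa * aa_length
            if poisson_noise:
                psms = float(rng.poisson(psms))
            out.append(
                PSMRecord(
                    protein_id=pid,
                    annotation=pid.removeprefix("P_") + "-like",
                    aa_length=aa_length,
                    psms=psms,
                    timepoint_h=t,
                )
            )
    return out


def simulate_read_counts(
    mag_profile: dict[str, float],
    total_reads: int,
    params: SimParams,
    lengths: dict[str, int] | None = None,
    sample_id: str = "S1",
) -> list[FeatureCount]:
    """Multinomial mapped reads with probabilities ∝ proportion x length.

    Length-weighting makes the RPM of the expectation recover the profile.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    props = np.array(list(mag_profile.values()), float)
    if not math.isclose(props.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("profile proportions must sum to 1")
    names = list(mag_profile)
    if lengths is None:
        lengths = {name: 2_000_000 for name in names}
    lens = np.array([lengths[name] for name in names], float)
    if np.any(lens <= 0):
        raise ValueError("lengths must be > 0")
    probs = props * lens
    probs /= probs.sum()
    rng = params.rng()
    counts = rng.multinomial(total_reads, probs)
    return [
        FeatureCount(
            feature_id=name,
            length=int(lengths[name]),
            mapped_reads=int(c),
            sample_id=sample_id,
        )
        for name, c in zip(names, counts)
    ]
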