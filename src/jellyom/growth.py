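"""Exponential-phase kinetics and the bacterial carbon budget.

The budget identity is BCD = BP + BR: carbon demand (DOC drawdown) splits
into biomass production (cell increase times per-cell carbon) and
respiration (the remainder). Growth efficiency BGE = 100 * BP / BCD.
Budgets are computed per replicate flask and only then aggregated, so the
treatment-mean BGE is a mean of per-flask ratios, not a ratio of means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import _fit
from .stoichiometry import ATOMIC_MASS, CellCarbonFactor, cells_to_carbon


class NoGrowthError(ValueError):
    """Raised when no exponential-growth window exists in a series."""


@dataclass(frozen=True)
class GrowthWindow:
    """Contiguous time window over which ln(cells) is linear in time."""

    t_start_h: float
    t_end_h: float
    n_points: int
    mu_per_h: float
    r_squared: float

    def __post_init__(self) -> None:
        if not self.t_end_h > self.t_start_h:
            raise ValueError("t_end_h must exceed t_start_h")
        if self.n_points < 3:
            raise ValueError("a growth window needs >= 3 points")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass
class CarbonBudget:
    """Per-replicate carbon budget in μg C L^-1 h^-1 (BB in μg C L^-1)."""

    replicate_id: str
    bcd_ugc_l_h: float
    bp_ugc_l_h: float
    br_ugc_l_h: float
    bge_pct: float | None
    mu_per_h: float
    bb_ugc_l: float
    flags: list[str] = field(default_factory=list)


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    flags: list[str] = field(default_factory=list)


#: Budget quantities aggregated across replicates, in report order.
BUDGET_QUANTITIES = ("bcd", "bb", "mu", "bp", "br", "bge")

_FIELD_OF = {
    "bcd": "bcd_ugc_l_h",
    "bb": "bb_ugc_l",
    "mu": "mu_per_h",
    "bp": "bp_ugc_l_h",
    "br": "br_ugc_l_h",
    "bge": "bge_pct",
}


def detect_exponential_window(times, cells) -> GrowthWindow:
    """Best log-linear window of >= 3 contiguous points before the peak.

    Among all contiguous windows ending at or before the abundance maximum,
    returns the one maximizing R^2 of ln(cells) vs time; ties are broken
    toward the longer window, then the earlier start. A window must have a
    positive slope; if none does (flat or decaying series), raises
    :class:`NoGrowthError`.
    """
    t = np.asarray(times, float)
    n = np.asarray(cells, float)
    if t.size < 4:
        raise ValueError("need >= 4 timepoints to detect an exponential window")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(n <= 0):
        raise ValueError("cell abundances must be > 0")

    ln_n = np.log(n)
    i_max = int(np.argmax(n))
    best: tuple[float, int, float, GrowthWindow] | None = None
    for end in range(2, i_max + 1):
        for start in range(0, end - 1):
            mu, r2 = _fit.ols_slope(t[start : end + 1], ln_n[start : end + 1])
            if mu <= 0:
                continue
            length = end - start + 1
            # sort key: higher r2, then longer, then earlier start
            key = (r2, length, -t[start])
            if best is None or key > (best[0], best[1], best[2]):
                window = GrowthWindow(
                    t_start_h=float(t[start]),
                    t_end_h=float(t[end]),
                    n_points=length,
                    mu_per_h=mu,
                    r_squared=min(r2, 1.0),
                )
                best = (r2, length, -t[start], window)
    if best is None:
        raise NoGrowthError("no window with positive log-linear slope found")
    return best[3]


def growth_rate(window: GrowthWindow) -> dict[str, float]:
    """Growth rate in both h^-1 and d^-1 for a detected window."""
    return {"mu_per_h": window.mu_per_h, "mu_per_d": 24.0 * window.mu_per_h}


def _window_slice(times, values, window: GrowthWindow):
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    mask = (t >= window.t_start_h - 1e-9) & (t <= window.t_end_h + 1e-9)
    if mask.sum() < 2:
        raise ValueError("series does not cover the growth window")
    return t[mask], v[mask]


def carbon_budget(
    doc_times,
    doc_umol_l,
    cell_times,
    cells_per_ml,
    window: GrowthWindow,
    factor: CellCarbonFactor | None = None,
    method: str = "ols",
    replicate_id: str = "R1",
) -> CarbonBudget:
    """Carbon budget of one flask over its exponential window.

    DOC enters in μmol C L^-1 (converted internally to μg C with the atomic
    mass of carbon); cells in cells mL^-1. BCD is the negated DOC slope,
    BP the cell slope times the per-cell carbon factor, BR the difference
    and BGE their percentage ratio. A non-positive BCD flags the budget as
    "no net consumption" and leaves BGE undefined.
    """
    factor = factor or CellCarbonFactor()
    td, doc = _window_slice(doc_times, doc_umol_l, window)
    tc, cells = _window_slice(cell_times, cells_per_ml, window)

    doc_ugc = doc * ATOMIC_MASS["C"]
    cells_per_l = cells * 1e3

    bcd = -_fit.fit_slope(td, doc_ugc, method)
    bp = _fit.fit_slope(tc, cells_per_l, method) * factor.fg_c_per_cell * 1e-9
    br = bcd - bp

    flags: list[str] = []
    if bcd <= 0:
        bge = None
        flags.append("no_net_consumption")
    else:
        bge = 100.0 * bp / bcd
        if bge > 100.0:
            flags.append("bge_above_100")

    bb = cells_to_carbon(float(cells_per_l[np.argmax(tc)]), factor)
    return CarbonBudget(
        replicate_id=replicate_id,
        bcd_ugc_l_h=bcd,
        bp_ugc_l_h=bp,
        br_ugc_l_h=br,
        bge_pct=bge,
        mu_per_h=window.mu_per_h,
        bb_ugc_l=bb,
        flags=flags,
    )


def two_sample_t_test(a, b) -> TTestResult:
    """Two-sided pooled-variance (homoscedastic) two-sample t-test.

    Degenerate zero-variance inputs follow fixed conventions: equal means
    give p = 1, unequal means give p = 0 with a flag.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each arm needs >= 2 values")
    df = int(a.size + b.size - 2)
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0)
        return TTestResult(
            t=math.copysign(math.inf, diff), df=df, p=0.0, flags=["zero_variance"]
        )
    t = diff / math.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p=p)


def welch_t_test(a, b) -> TTestResult:
    """Welch's unequal-variance alternative (diagnostic)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each arm needs >= 2 values")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(t=float(res.statistic), df=int(res.df), p=float(res.pvalue))


def aggregate_budgets(
    budgets: list[CarbonBudget],
    control: list[CarbonBudget],
    welch: bool = False,
) -> dict:
    """Treatment-level mean ± SD per budget quantity plus p-value vs control.

    BGE is averaged across replicate-level ratios (never recomputed from
    mean BP / mean BCD); the ratio-of-means diagnostic is reported
    separately. Replicates with undefined BGE are dropped from the BGE
    aggregation only.
    """
    for arm, name in ((budgets, "treatment"), (control, "control")):
        if len(arm) < 2:
            raise ValueError(f"{name} arm needs >= 2 replicates for SD and t-test")

    test = welch_t_test if welch else two_sample_t_test
    summary: dict = {"n_treatment": len(budgets), "n_control": len(control), "quantities": {}}
    for q in BUDGET_QUANTITIES:
        attr = _FIELD_OF[q]
        va = np.asarray([getattr(x, attr) for x in budgets if getattr(x, attr) is not None], float)
        vb = np.asarray([getattr(x, attr) for x in control if getattr(x, attr) is not None], float)
        entry = {
            "mean": float(va.mean()) if va.size else None,
            "sd": float(va.std(ddof=1)) if va.size > 1 else None,
            "control_mean": float(vb.mean()) if vb.size else None,
            "control_sd": float(vb.std(ddof=1)) if vb.size > 1 else None,
            "n": int(va.size),
            "n_control": int(vb.size),
        }
        if va.size >= 2 and vb.size >= 2:
            res = test(va, vb)
            entry["p_value"] = res.p
        else:
            entry["p_value"] = None
        summary["quantities"][q] = entry

    # diagnostic: the aggregation-order alternative for BGE
    bcd_mean = summary["quantities"]["bcd"]["mean"]
    bp_mean = summary["quantities"]["bp"]["mean"]
    if bcd_mean:
        summary["bge_ratio_of_means_pct"] = 100.0 * bp_mean / bcd_mean
    else:
        summary["bge_ratio_of_means_pct"] = None
    return summary
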