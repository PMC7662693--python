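"""Slope estimation shared by leaching, growth and pool modules."""

from __future__ import annotations

import numpy as np

METHODS = ("ols", "endpoint")


def _check(times: np.ndarray, values: np.ndarray, min_points: int = 2) -> None:
    times = np.asarray(times, float)
    if times.size < min_points:
        raise ValueError(f"need >= {min_points} timepoints, got {times.size}")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")


def ols_slope(times: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R^2 of values vs time.

    R^2 is defined as 0 when the response has zero variance.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    _check(t, y)
    tc = t - t.mean()
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst == 0.0:
        return 0.0, 0.0
    slope = float((tc @ yc) / (tc @ tc))
    resid = yc - slope * tc
    r2 = 1.0 - float(resid @ resid) / sst
    return slope, r2


def endpoint_slope(times: np.ndarray, values: np.ndarray) -> float:
    """First-to-last difference quotient."""
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    _check(t, y)
    return float((y[-1] - y[0]) / (t[-1] - t[0]))


def fit_slope(times, values, method: str = "ols") -> float:
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if method == "endpoint":
        return endpoint_slope(times, values)
    return ols_slope(times, values)[0]


def best_prefix_slope(times, values, min_points: int = 3) -> tuple[float, int]:
    """OLS slope over the contiguous prefix (>= min_points) maximizing R^2.

    Used for saturating series: returns (slope, n_points_used). Ties go to
    the longer prefix.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    _check(t, y, min_points)
    best = (-np.inf, min_points, 0.0)  # (r2, n, slope)
    for n in range(min_points, t.size + 1):
        slope, r2 = ols_slope(t[:n], y[:n])
        if r2 >= best[0]:  # >= prefers longer prefixes on ties
            best = (r2, n, slope)
    return best[2], best[1]
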