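"""Elemental unit conversions and shared arithmetic.

All internal arithmetic keeps full floating-point precision; rounding is a
display concern handled by :func:`round_sig` at report time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

#: IUPAC atomic masses (g mol^-1) for the elements tracked by the pipeline.
ATOMIC_MASS: dict[str, float] = {"C": 12.011, "N": 14.007, "P": 30.974}


class UnknownElementError(KeyError):
    """Raised for element symbols outside the supported {C, N, P} set."""


class NetAccumulationWarning(UserWarning):
    """Emitted when a pool grew instead of being consumed."""


@dataclass(frozen=True)
class CellCarbonFactor:
    """Per-cell carbon content used to convert abundances to biomass.

    Parameters
    ----------
    fg_c_per_cell : float
        Femtograms of carbon per cell. Default 19.8.
    """

    fg_c_per_cell: float = 19.8

    def __post_init__(self) -> None:
        if not self.fg_c_per_cell > 0:
            raise ValueError("fg_c_per_cell must be > 0")


def umol_to_ug(amount: float, element: str) -> float:
    """Convert a molar amount (μmol) of an element to mass (μg).

    Linear in ``amount``; negative amounts pass through (signed rates).
    """
    if element not in ATOMIC_MASS:
        raise UnknownElementError(
            f"unknown element {element!r}; expected one of {sorted(ATOMIC_MASS)}"
        )
    if not math.isfinite(amount):
        raise ValueError("amount must be finite")
    return amount * ATOMIC_MASS[element]


def molar_cn(c_wt_pct: float, n_wt_pct: float) -> float:
    """Molar C:N ratio from carbon and nitrogen weight percentages.

    Invariant under common rescaling of both inputs, so any pair of
    mass-proportional units (wt%, μg, mg) works.
    """
    if c_wt_pct <= 0:
        raise ValueError("carbon weight percentage must be > 0")
    if n_wt_pct <= 0:
        raise ValueError("nitrogen weight percentage must be > 0")
    return (c_wt_pct / ATOMIC_MASS["C"]) / (n_wt_pct / ATOMIC_MASS["N"])


def cells_to_carbon(
    cells_per_l: float, factor: CellCarbonFactor | None = None
) -> float:
    """Convert cell abundance (cells L^-1) to biomass carbon (μg C L^-1)."""
    if cells_per_l < 0:
        raise ValueError("cell abundance must be >= 0")
    factor = factor or CellCarbonFactor()
    return cells_per_l * factor.fg_c_per_cell * 1e-9  # fg -> ug


def carbon_to_cells(ug_c_per_l: float, factor: CellCarbonFactor | None = None) -> float:
    """Inverse of :func:`cells_to_carbon`."""
    factor = factor or CellCarbonFactor()
    return ug_c_per_l / (factor.fg_c_per_cell * 1e-9)


def fraction_consumed(initial: float, final: float) -> float:
    """Percentage of an initial pool consumed by a later timepoint.

    Returns ``100 * (initial - final) / initial``. Negative results (net
    accumulation) are returned unchanged with a
    :class:`NetAccumulationWarning` rather than being clamped.
    """
    if initial <= 0:
        raise ValueError("initial pool must be > 0")
    if final < 0:
        raise ValueError("final pool must be >= 0")
    # formulated so fraction_consumed(i, 0) is exactly 100 for any i
    pct = 100.0 - 100.0 * final / initial
    if pct < 0:
        warnings.warn(
            f"pool grew from {initial} to {final}: net accumulation",
            NetAccumulationWarning,
            stacklevel=2,
        )
    return pct


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures (display only)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
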