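"""Daily single-layer water balance with macropore bypass.

A spilling-bucket at daily resolution: net precipitation is split into
runoff, matrix infiltration and macropore bypass; matrix water above field
capacity spills to the subsoil the same day; stored water is allocated to the
five pore-size classes smallest-first, so at most one class is partially
filled.  Unit bridging: 1 mm of water over 1 m^2 is 1 l; divided by the layer
thickness (m) it becomes l per m^3 of soil, the unit of the pore volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_state import ValidationError
from .porosity import INAC, BACT, MICRO, MESO, MACRO, PoreState

__all__ = [
    "WaterState",
    "net_precipitation",
    "macropore_capacity",
    "matrix_infiltration_capacity",
    "field_capacity",
    "partition_water",
    "drainage",
    "allocate_water_to_classes",
    "water_step",
]


@dataclass
class WaterState:
    """Layer water volume (l m^-3) and its allocation across pore classes.

    ``w`` holds per-class water volumes; ``partial_class`` is the index of
    the single partially filled class (None when every non-empty class is
    exactly full or exactly empty at a boundary, or the soil is saturated).
    """

    sw: float
    w: np.ndarray
    partial_class: int | None = None
    sa_macro: float = 0.0
    i_max_mat: float = 50.0  # mm day^-1
    i_max_mat_subsoil: float = 50.0  # mm day^-1

    def aerated(self, pore: PoreState) -> np.ndarray:
        """Air-filled volume per class (l m^-3)."""
        return np.maximum(pore.pv - self.w, 0.0)

    def copy(self) -> "WaterState":
        out = WaterState(self.sw, self.w.copy(), self.partial_class,
                         self.sa_macro, self.i_max_mat, self.i_max_mat_subsoil)
        return out


def net_precipitation(p: float, e: float) -> float:
    """P_net = P - E (mm day^-1); negative values draw down storage."""
    if p < 0 or e < 0:
        raise ValidationError("precipitation and evapotranspiration must be >= 0")
    return p - e


def macropore_capacity(pv_macro: float, i_max_mat_below: float, thickness: float = 1.0) -> float:
    """Maximal infiltration through macropores, mm day^-1.

    The macropore volume (converted from l m^-3 to mm via the layer
    thickness) is available as same-day storage, plus whatever the layer
    below can accept.
    """
    if pv_macro < 0 or i_max_mat_below < 0:
        raise ValidationError("inputs must be >= 0")
    return pv_macro * thickness + i_max_mat_below


def matrix_infiltration_capacity(f_clay: float) -> float:
    """Matrix infiltration capacity I_maxMat (mm day^-1) from clay fraction.

    Empirical: 60*exp(-6*fClay) — ~50 mm/day for a sandy soil, ~24 at 15%
    clay.  Used only when the site configuration does not state I_maxMat.
    """
    return 60.0 * float(np.exp(-6.0 * f_clay))


def field_capacity(pore: PoreState, include_meso: bool = False) -> float:
    """Water content at field capacity (l m^-3): macropores (and by default
    mesopores) drained."""
    fc = float(pore.pv[INAC] + pore.pv[BACT] + pore.pv[MICRO])
    if include_meso:
        fc += float(pore.pv[MESO])
    return fc


def partition_water(
    p_net: float,
    i_max_mat: float,
    i_max_por: float,
    sa_macro: float,
    pv_tot: float,
    sw: float,
    thickness: float = 1.0,
):
    """Split positive net precipitation into (runoff, matrix_fill, bypass), mm day^-1.

    runoff = max(0, P_net - (I_maxPor + I_maxMat)); the matrix fill is limited
    by remaining pore space, by the matrix infiltration capacity and by the
    non-macropore share of the input; the rest bypasses through macropores.
    The identity runoff + matrix_fill + bypass = max(P_net, 0) holds exactly.
    """
    if min(i_max_mat, i_max_por) < 0:
        raise ValidationError("capacities must be >= 0")
    if p_net <= 0.0:
        return 0.0, 0.0, 0.0
    runoff = max(0.0, p_net - (i_max_por + i_max_mat))
    p_eff = p_net - runoff
    matrix_fill = min(
        (pv_tot - sw) * thickness,
        i_max_mat * (1.0 - sa_macro),
        p_eff * (1.0 - sa_macro),
    )
    matrix_fill = max(matrix_fill, 0.0)
    bypass = p_eff - matrix_fill
    return runoff, matrix_fill, bypass


def drainage(
    p_net: float,
    sa_macro: float,
    pv_tot: float,
    sw: float,
    i_max_mat: float,
    fc: float,
    i_max_por: float | None = None,
    thickness: float = 1.0,
    literal: bool = False,
):
    """Water leaving the layer (mm day^-1).

    Default: exact mass balance — macropore bypass plus the matrix spill
    above field capacity; conserves water in every regime.  With
    ``literal=True`` the printed bucket formula
    D = P_net*SA_macro + P_net - min(PV - SW, I_maxMat*(1-SA), P_net*(1-SA))
    is evaluated instead (for comparison only; it double-counts part of
    P_net in some regimes).
    """
    if literal:
        if p_net <= 0.0:
            return 0.0
        m = min(
            (pv_tot - sw) * thickness,
            i_max_mat * (1.0 - sa_macro),
            p_net * (1.0 - sa_macro),
        )
        return p_net * sa_macro + p_net - max(m, 0.0)
    if i_max_por is None:
        i_max_por = float("inf")
    _, matrix_fill, bypass = partition_water(
        p_net, i_max_mat, i_max_por, sa_macro, pv_tot, sw, thickness
    )
    sw_after = sw + matrix_fill / thickness
    spill = max(0.0, sw_after - fc)
    return bypass + spill * thickness


def allocate_water_to_classes(sw: float, pore: PoreState) -> WaterState:
    """Fill pore classes smallest-first so at most one class is partial.

    Order: inaccessible -> bacterial -> micro -> meso -> macro, mimicking
    matric-potential ordering.  SW above total porosity is clipped with a
    warning (the excess is the caller's to route to drainage).
    """
    if sw < 0:
        raise ValidationError("soil water must be >= 0")
    pv_tot = pore.pv_tot
    if sw > pv_tot * (1.0 + 1e-12):
        warnings.warn(
            f"soil water {sw:.3f} above total porosity {pv_tot:.3f}; clipped",
            RuntimeWarning,
            stacklevel=2,
        )
        sw = pv_tot
    w = np.zeros(5)
    rem = sw
    for c in range(5):
        w[c] = min(rem, pore.pv[c])
        rem -= w[c]
    partial = None
    for c in range(5):
        if pore.pv[c] > 0.0 and w[c] < pore.pv[c]:
            partial = c
            break
    return WaterState(sw=float(sw), w=w, partial_class=partial,
                      sa_macro=min(1.0, pore.pv[MACRO] / 1000.0))


def water_step(
    water: WaterState,
    pore: PoreState,
    p_mm: float,
    e_mm: float,
    thickness: float,
    fc_includes_meso: bool = False,
):
    """One daily water-balance step.

    Returns ``(new_water, runoff_mm, drainage_mm)``.  Positive net
    precipitation is partitioned into runoff / matrix fill / macropore
    bypass; matrix water above field capacity spills the same day.  Negative
    net precipitation (E > P) extracts water from storage down to the wilting
    point (the water held in inaccessible pores).
    """
    sw = min(water.sw, pore.pv_tot)  # porosity may have shrunk overnight
    sa_macro = min(1.0, pore.pv[MACRO] / 1000.0)
    fc = field_capacity(pore, include_meso=fc_includes_meso)
    p_net = net_precipitation(p_mm, e_mm)
    runoff_mm = 0.0
    drain_mm = 0.0
    if p_net > 0.0:
        i_max_por = macropore_capacity(pore.pv[MACRO], water.i_max_mat_subsoil, thickness)
        runoff_mm, matrix_fill, bypass = partition_water(
            p_net, water.i_max_mat, i_max_por, sa_macro, pore.pv_tot, sw, thickness
        )
        sw += matrix_fill / thickness
        spill = max(0.0, sw - fc)
        sw -= spill
        drain_mm = bypass + spill * thickness
    elif p_net < 0.0:
        floor = min(sw, pore.pv[INAC])
        sw = max(floor, sw + p_net / thickness)
    out = allocate_water_to_classes(sw, pore)
    out.i_max_mat = water.i_max_mat
    out.i_max_mat_subsoil = water.i_max_mat_subsoil
    return out, runoff_mm, drain_mm
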