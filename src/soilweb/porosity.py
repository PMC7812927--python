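"""Soil structure: particle density, total porosity, aggregation, burrows and
the daily five-class pore-size distribution.

Total porosity is the sum of a constant textural component, an aggregation
component driven by fungal/mycorrhizal biomass binding SOM, and the biopore
volume dug by ecosystem engineers (of which a fraction ``f_pv`` adds to the
total, the rest being compensated by compaction of mesopores).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_state import PORE_CLASSES, ValidationError

__all__ = [
    "PoreState",
    "particle_density",
    "total_porosity_percent",
    "texture_pore_volumes",
    "aggregation_fraction",
    "aggregation_porosity",
    "burrow_volume_update",
    "pore_size_distribution",
]

# indices into the five-class arrays
INAC, BACT, MICRO, MESO, MACRO = range(5)


@dataclass
class PoreState:
    """Pore volume per size class (l m^-3) with its structural decomposition.

    ``pv`` is the current volume per class; ``pv_text`` the constant textural
    component; ``pv_b`` the burrow (biopore) volume; ``pv_ag`` the aggregation
    porosity.  ``clamped_deficit`` records volume lost to the >= 0 clamp of
    the class identities (normally zero).
    """

    pv: np.ndarray
    pv_text: np.ndarray
    pv_b: float = 0.0
    pv_ag: float = 0.0
    f_pv: float = 0.5
    pv_bmax: float = 50.0
    ve_ratio: float = 0.05
    tpv_b: float = 1.0 / 3650.0
    k_ag: float = 2.0
    c_ag: float = 10.0
    pv_ag_cap: float = 20.0
    clamped_deficit: float = 0.0

    @classmethod
    def from_textural(cls, pv_text, **params) -> "PoreState":
        pv_text = np.asarray(pv_text, dtype=float)
        if pv_text.shape != (5,):
            raise ValidationError("pv_text must have five classes")
        if (pv_text < 0).any():
            raise ValidationError("textural pore volumes must be >= 0")
        return cls(pv=pv_text.copy(), pv_text=pv_text, **params)

    @property
    def pv_tot(self) -> float:
        return float(self.pv.sum())

    def as_dict(self) -> dict:
        return {c: float(v) for c, v in zip(PORE_CLASSES, self.pv)}

    def copy(self) -> "PoreState":
        out = PoreState(**{k: getattr(self, k) for k in self.__dataclass_fields__})
        out.pv = self.pv.copy()
        out.pv_text = self.pv_text.copy()
        return out


def particle_density(pct_som: float, d_som: float = 1.35, d_m: float = 2.65) -> float:
    """Soil particle density D_s (g cm^-3) from the SOM mass percentage.

    Harmonic mixing of mineral (2.65 g cm^-3) and organic (1.35 g cm^-3)
    particle densities: D_s = 100 / (%SOM/D_SOM + (100-%SOM)/D_m).
    """
    if not 0.0 <= pct_som <= 100.0:
        raise ValidationError(f"SOM percentage out of [0,100]: {pct_som}")
    return 100.0 / (pct_som / d_som + (100.0 - pct_som) / d_m)


def total_porosity_percent(d_s: float, d_b: float) -> float:
    """Total porosity P_% = (D_s - D_b)/D_s * 100, in (0, 100)."""
    if not 0.0 < d_b < d_s:
        raise ValidationError(f"need 0 < D_b < D_s, got D_b={d_b}, D_s={d_s}")
    return (d_s - d_b) / d_s * 100.0


def texture_pore_volumes(p_pct: float, pct_sand: float, pct_clay: float) -> np.ndarray:
    """Split total porosity into textural class volumes (l m^-3).

    A simple pedotransfer table: the fine-pore share (inaccessible, bacterial,
    micro) grows linearly with clay fraction, the remainder splits 85/15
    between meso- and macropores.  Calibrated to give a sandy forest topsoil a
    fine-pore share of ~40% of porosity and a clay-rich soil (~15% clay) close
    to 70%.
    """
    if not 0.0 < p_pct < 100.0:
        raise ValidationError("total porosity must be in (0,100) %")
    f_clay = pct_clay / 100.0
    pv_tot = p_pct * 10.0  # % of 1 m^3 -> l m^-3
    f_inac = 0.05 + 0.9 * f_clay
    f_bact = 0.10 + 0.5 * f_clay
    f_micro = 0.20 + 0.7 * f_clay
    rest = 1.0 - (f_inac + f_bact + f_micro)
    if rest < 0.0:
        raise ValidationError("clay fraction too high for the pedotransfer table")
    fracs = np.array([f_inac, f_bact, f_micro, 0.85 * rest, 0.15 * rest])
    return pv_tot * fracs


def aggregation_fraction(b_fung: float, b_myc: float, b_som: float, c_ag: float = 10.0) -> float:
    """Aggregated fraction of SOM: Ag = min(1, c*(B_fung + B_myc)/B_SOM).

    B_SOM = 0 is a documented degenerate case returning 0 (nothing to bind).
    """
    if b_fung < 0 or b_myc < 0:
        raise ValidationError("biomasses must be >= 0")
    if b_som <= 0.0:
        return 0.0
    return min(1.0, c_ag * (b_fung + b_myc) / b_som)


def aggregation_porosity(
    ag: float, b_som: float, k_ag: float = 2.0, pv_ag_cap: float = 20.0
) -> float:
    """Aggregation porosity PV_Ag = min(cap, k*Ag*B_SOM), l m^-3.

    The cap (default 20 l m^-3, i.e. 2% of the soil volume) bounds the extra
    porosity aggregation can contribute.
    """
    if not 0.0 <= ag <= 1.0:
        raise ValidationError("Ag must be in [0,1]")
    return min(pv_ag_cap, k_ag * ag * b_som)


def burrow_volume_update(
    pv_b_prev: float,
    b_eng: float,
    pv_macro: float,
    pv_textmacro: float,
    pv_bmax: float = 50.0,
    ve_ratio: float = 0.05,
    tpv_b: float = 1.0 / 3650.0,
) -> float:
    """Daily burrow volume (l m^-3).

    Burrows grow with engineer biomass (VE_ratio * B_eng, up to PV_Bmax) and
    otherwise decay geometrically at the turnover rate tPV_B (default
    1/3650 day^-1, a 10-year mean lifespan):
    PV_B = max(min(PV_Bmax, VE_ratio*B_eng), (PV_macro - PV_textmacro)*(1 - tPV_B)).
    """
    if min(pv_b_prev, b_eng, pv_macro) < 0:
        raise ValidationError("inputs must be >= 0")
    dug = min(pv_bmax, ve_ratio * b_eng)
    relict = (pv_macro - pv_textmacro) * (1.0 - tpv_b)
    return max(dug, relict, 0.0)


def pore_size_distribution(
    ag: float, pv_b: float, b_som: float, pore: PoreState
) -> PoreState:
    """Recompute the five class volumes from aggregation and burrow state.

    macro = text_macro + PV_B
    meso  = text_meso - (1 - f_pv)*PV_B - (Ag/2)*text_meso
    micro = text_micro + capped k*(Ag/2)*B_SOM + (Ag/4)*text_meso
    bact  = text_bact  + capped k*(Ag/2)*B_SOM + (Ag/4)*text_meso
    inac  = text_inac

    The aggregation porosity added to micro+bacterial classes is capped so the
    combined extra stays within ``pv_ag_cap`` (split equally).  Classes are
    clamped at zero; any clamped deficit is recorded on the returned state and
    a warning issued (the class volumes then no longer satisfy the
    total-porosity identity).
    """
    if not 0.0 <= ag <= 1.0:
        raise ValidationError("Ag must be in [0,1]")
    if pv_b > pore.pv_bmax + 1e-9:
        raise ValidationError("PV_B exceeds PV_Bmax")
    t = pore.pv_text
    ag_term = min(pore.k_ag * (ag / 2.0) * b_som, pore.pv_ag_cap / 2.0)
    meso_shift = (ag / 4.0) * t[MESO]
    pv = np.empty(5)
    pv[INAC] = t[INAC]
    pv[BACT] = t[BACT] + ag_term + meso_shift
    pv[MICRO] = t[MICRO] + ag_term + meso_shift
    pv[MESO] = t[MESO] - (1.0 - pore.f_pv) * pv_b - (ag / 2.0) * t[MESO]
    pv[MACRO] = t[MACRO] + pv_b

    deficit = float(-pv[pv < 0].sum()) if (pv < 0).any() else 0.0
    if deficit > 0.0:
        warnings.warn(
            f"negative pore volume clamped (deficit {deficit:.3g} l m^-3)",
            RuntimeWarning,
            stacklevel=2,
        )
        pv = np.maximum(pv, 0.0)

    out = pore.copy()
    out.pv = pv
    out.pv_b = pv_b
    out.pv_ag = 2.0 * ag_term
    out.clamped_deficit = deficit
    return out
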