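"""Multiplicative modifiers on the maximum growth rate g_max.

Moisture, temperature, pH, substrate C:N and substrate recalcitrance each
yield a dimensionless modifier in [0, 1]; the combined effect is their
product (or, optionally, the single most limiting one).  Respiration uses the
same Q10 temperature curve but without the plateau, so above the optimum
respiration keeps rising while growth does not, eventually causing a net
biomass loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_state import ValidationError
from .hydrology import WaterState
from .porosity import PoreState

__all__ = [
    "ModifierSet",
    "moisture_modifier_total",
    "moisture_modifier_by_class",
    "litter_moisture",
    "temperature_modifier",
    "respiration_temperature_factor",
    "ph_modifier_microbe",
    "ph_gmax_engineers",
    "cn_modifier",
    "recalcitrance_modifier",
    "combine",
]


@dataclass
class ModifierSet:
    """The five growth-rate modifiers for one guild (each in [0, 1])."""

    m_t: float = 1.0
    m_ph: float = 1.0
    m_cn: float = 1.0
    m_rec: float = 1.0
    m_h2o: float = 1.0
    combine_mode: str = "product"

    def __post_init__(self):
        for name in ("m_t", "m_ph", "m_cn", "m_rec", "m_h2o"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} out of [0,1]: {v}")
        if self.combine_mode not in ("product", "most-limiting"):
            raise ValidationError(f"unknown combine mode {self.combine_mode!r}")

    @property
    def m_tot(self) -> float:
        return combine(self)


def moisture_modifier_total(v: float, p_vol: float) -> float:
    """Overall hydration modifier: 4x(1-x) below half saturation, else 1.

    x = V/P_vol.  Continuous at x = 0.5 (both branches give 1).  An empty
    habitat (P_vol = 0) gives 0.
    """
    if p_vol <= 0.0:
        return 0.0
    if not 0.0 <= v <= p_vol * (1.0 + 1e-12):
        raise ValidationError(f"water volume {v} outside [0, {p_vol}]")
    x = v / p_vol
    if x < 0.5:
        return 4.0 * x * (1.0 - x)
    return 1.0


def moisture_modifier_by_class(
    water: WaterState, pore: PoreState, class_above_numerator: str = "water"
) -> np.ndarray:
    """Per-pore-class moisture modifier (length-5 array).

    Activity concentrates at the wetting front: the partially filled class
    gets the aerated share of the overall modifier, the class one size above
    gets the complementary (water-filled) share, saturated classes below and
    dry classes further above get 0.  ``class_above_numerator="aerated"``
    switches the class-above weighting to the aerated share (alternative
    reading of the weighting; default is as printed).
    """
    if class_above_numerator not in ("water", "aerated"):
        raise ValidationError("class_above_numerator must be 'water' or 'aerated'")
    m = np.zeros(5)
    m_tot = moisture_modifier_total(water.sw, pore.pv_tot)
    p = water.partial_class
    if p is None or m_tot == 0.0:
        return m
    w_p = water.w[p]
    a_p = pore.pv[p] - w_p
    tot = a_p + w_p
    if tot <= 0.0:
        return m
    m[p] = (a_p / tot) * m_tot
    if p + 1 < 5 and pore.pv[p + 1] > 0.0:
        share = w_p if class_above_numerator == "water" else a_p
        m[p + 1] = (share / tot) * m_tot
    return m


def litter_moisture(class_m: np.ndarray, pore: PoreState) -> float:
    """Moisture modifier for surface litter: the microbial-habitat value.

    Surface litter is outside the soil matrix; its humidity is taken to track
    the soil below, so the pore-volume-weighted moisture modifier over the
    microbially inhabited classes (bacterial and larger) is used.
    """
    pv = pore.pv[1:]
    tot = float(pv.sum())
    if tot <= 0.0:
        return 0.0
    return float((pv * class_m[1:]).sum() / tot)


def temperature_modifier(t: float, t_min: float, t_opt: float, t_max: float, q10: float) -> float:
    """Q10 growth curve with a plateau above the optimum.

    0 outside [t_min, t_max); Q^((T - T_opt)/10) between t_min and t_opt;
    1 on the plateau [t_opt, t_max).
    """
    if not (t_min < t_opt < t_max):
        raise ValidationError("need t_min < t_opt < t_max")
    if t < t_min or t >= t_max:
        return 0.0
    if t < t_opt:
        return float(q10 ** ((t - t_opt) / 10.0))
    return 1.0


def respiration_temperature_factor(
    t: float, t_opt: float, q10: float, t_min: float = 0.0, t_max: float = 40.0
) -> float:
    """Respiration Q10 factor: same curve but no plateau, may exceed 1."""
    if not (t_min < t_opt < t_max):
        raise ValidationError("need t_min < t_opt < t_max")
    if t < t_min or t >= t_max:
        return 0.0
    return float(q10 ** ((t - t_opt) / 10.0))


def ph_modifier_microbe(ph: float, guild: str) -> float:
    """pH modifier for fungi (threshold 8) and bacteria (threshold 3).

    A ten-fold reduction in g_max per pH unit beyond the threshold, clamped
    at 1 inside the tolerated range.
    """
    if not 0.0 < ph < 14.0:
        raise ValidationError(f"pH out of (0,14): {ph}")
    if guild == "fungi":
        if ph >= 8.1:
            return min(1.0, 1.0 / ((ph - 8.0) * 10.0))
        return 1.0
    if guild == "bacteria":
        if ph <= 2.9:
            return min(1.0, 1.0 / ((3.0 - ph) * 10.0))
        return 1.0
    raise ValidationError(f"guild must be 'fungi' or 'bacteria', got {guild!r}")


def ph_gmax_engineers(g_max: float, ph: float) -> float:
    """Engineer g_max under pH: 0 below 3, linear ramp on [3, 5), g_max above."""
    if g_max < 0:
        raise ValidationError("g_max must be >= 0")
    if ph < 3.0:
        return 0.0
    if ph < 5.0:
        return (g_max / 2.0) * (ph - 3.0)
    return g_max


def cn_modifier(cn_consumer: float, cn_substrate: float, p_m_cn: float) -> float:
    """Substrate C:N modifier: min(1, (CN_consumer/CN_substrate)^p_mCN)."""
    if cn_consumer <= 0 or cn_substrate <= 0:
        raise ValidationError("C:N ratios must be > 0")
    if not 0.0 <= p_m_cn <= 1.0:
        raise ValidationError("p_mCN must be in [0,1]")
    return min(1.0, (cn_consumer / cn_substrate) ** p_m_cn)


def recalcitrance_modifier(rec: float, p_m_rec: float) -> float:
    """Recalcitrance modifier: min(1, 1 - p_mRec*Rec); linear so decay of a
    fully recalcitrant substrate stops only at p_mRec = 1."""
    if not 0.0 <= rec <= 1.0:
        raise ValidationError("Rec must be in [0,1]")
    if not 0.0 <= p_m_rec <= 1.0:
        raise ValidationError("p_mRec must be in [0,1]")
    return min(1.0, 1.0 - p_m_rec * rec)


def combine(mods: ModifierSet) -> float:
    """Total modifier: product of components, or the minimum in
    most-limiting mode."""
    parts = (mods.m_t, mods.m_ph, mods.m_cn, mods.m_rec, mods.m_h2o)
    if mods.combine_mode == "most-limiting":
        return min(parts)
    out = 1.0
    for p in parts:
        out *= p
    return out
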