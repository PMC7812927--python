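"""Dissolved organic matter (DOM) production, adsorption and leaching.

DOM is produced as a fixed fraction of total respiration (high biological
activity releases soluble carbon) plus direct root exudation.  The daily
dissolved/adsorbed partition is an equilibrium set by the adsorption
coefficient K_D of the soil (more clay and lower pH both immobilize DOM);
the dissolved concentration leaves the layer with the draining water.
"""

from __future__ import annotations

from .core_state import ValidationError

__all__ = [
    "dom_production",
    "adsorption_coefficient",
    "dissolved_fraction",
    "dom_leaching",
]


def dom_production(c_exud: float, r_tot: float, f_dom: float) -> float:
    """Daily DOM production: exudation plus a fraction of total respiration."""
    if min(c_exud, r_tot, f_dom) < 0:
        raise ValidationError("inputs must be >= 0")
    return c_exud + f_dom * r_tot


def adsorption_coefficient(
    ph: float,
    f_clay: float,
    a_kd: float = 0.001226,
    b_kd: float = 0.000212,
    c_kd: float = 0.00374,
) -> float:
    """DOM adsorption coefficient K_D (m^3 per kg soil): a - b*pH + c*fClay."""
    return a_kd - b_kd * ph + c_kd * f_clay


def dissolved_fraction(k_d: float, soil_mass: float) -> float:
    """Fraction of the DOM pool in solution at equilibrium.

    With DOM_ad = K_D * soil_mass * DOM_dis, the dissolved share is
    1 / (1 + K_D * M) where M is the dry soil mass per m^3 (kg).
    """
    if soil_mass < 0:
        raise ValidationError("soil mass must be >= 0")
    return 1.0 / (1.0 + max(k_d, 0.0) * soil_mass)


def dom_leaching(
    dom: float, k_d: float, soil_mass: float, sw: float, drainage: float
) -> float:
    """DOM leached with drainage (g C m^-3 day^-1).

    The dissolved concentration (dissolved DOM / soil water) times the
    draining water volume (l m^-3 day^-1), capped at the available pool.
    """
    if min(dom, sw, drainage) < 0:
        raise ValidationError("inputs must be >= 0")
    if sw <= 0.0 or drainage <= 0.0:
        return 0.0
    conc = dom * dissolved_fraction(k_d, soil_mass) / sw
    return min(dom, conc * drainage)
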