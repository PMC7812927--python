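"""Shared domain types, carbon accounting identities and state initialization.

The model tracks 12 dynamic carbon pools, all in g C m^-3 of soil: nine
food-web guilds (bacteria, fungi, mycorrhiza, bacterivores, fungivores,
detritivores, ecosystem engineers, herbivores, predators), surface litter,
soil organic matter (SOM) and dissolved organic matter (DOM).  Roots and
above-ground litter production are external boundary inputs; respired CO2,
leached DOM and bioturbation exports are cumulative diagnostics so that total
carbon closes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np

__all__ = [
    "GUILDS",
    "POOLS",
    "PORE_CLASSES",
    "SIZE_CLASS_ACCESS",
    "ConfigurationError",
    "ValidationError",
    "PoolVector",
    "GuildParams",
    "DietLink",
    "LitterQuality",
    "SoilTexture",
    "ExternalInputs",
    "SiteConfig",
    "init_state",
    "total_carbon",
]

#: Food-web guilds, in canonical order.
GUILDS = (
    "bacteria",
    "fungi",
    "mycorrhiza",
    "bacterivores",
    "fungivores",
    "detritivores",
    "engineers",
    "herbivores",
    "predators",
)

#: All dynamic carbon pools, in canonical order (guilds first).
POOLS = GUILDS + ("litter", "som", "dom")

#: Pore size classes from smallest to largest.  Diameter bounds (um):
#: inaccessible < 0.1, bacterial 0.1-2, micro 2-30, meso 30-1500, macro > 1500.
PORE_CLASSES = ("inaccessible", "bacterial", "micro", "meso", "macro")

#: Pore classes (indices into PORE_CLASSES) reachable by each body-size class.
#: Ecosystem engineers override this: they ingest bulk soil and reach every
#: class except the inaccessible one.
SIZE_CLASS_ACCESS = {
    "bacteria": (1, 2, 3, 4),
    "micro": (2, 3, 4),
    "meso": (3, 4),
    "macro": (3, 4),
}

#: Non-guild substrates a diet link may point at.  "roots" is the fixed
#: boundary pool grazed by herbivores.
EXTRA_SUBSTRATES = ("litter", "som", "roots")


class ConfigurationError(ValueError):
    """A required configuration field is missing or unparsable."""


class ValidationError(ValueError):
    """A configuration or state value violates a model invariant."""


@dataclass
class PoolVector:
    """Dynamic carbon state (g C m^-3) plus cumulative flux diagnostics.

    ``co2_cum`` is cumulative respired CO2 (net of the fraction diverted to
    DOM production), ``dom_leached_cum`` cumulative DOM leached below the
    layer, ``bioturb_export_cum`` cumulative litter+SOM exported by
    bioturbation and ``inputs_cum`` cumulative external carbon inputs
    (litter fall, root litter, exudation, mycorrhizal allocation and root
    carbon grazed by herbivores).
    """

    bacteria: float = 0.0
    fungi: float = 0.0
    mycorrhiza: float = 0.0
    bacterivores: float = 0.0
    fungivores: float = 0.0
    detritivores: float = 0.0
    engineers: float = 0.0
    herbivores: float = 0.0
    predators: float = 0.0
    litter: float = 0.0
    som: float = 0.0
    dom: float = 0.0
    co2_cum: float = 0.0
    dom_leached_cum: float = 0.0
    bioturb_export_cum: float = 0.0
    inputs_cum: float = 0.0

    def as_array(self) -> np.ndarray:
        """The 12 dynamic pools as a float array in canonical order."""
        return np.array([getattr(self, p) for p in POOLS], dtype=float)

    def set_pools(self, values: Sequence[float]) -> None:
        for name, v in zip(POOLS, values):
            setattr(self, name, float(v))

    def validate(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValidationError(f"pool {f.name!r} is not finite: {v}")
            if f.name in POOLS and v < 0:
                raise ValidationError(f"pool {f.name!r} is negative: {v}")

    def copy(self) -> "PoolVector":
        return PoolVector(**{f.name: getattr(self, f.name) for f in dc_fields(self)})


@dataclass
class DietLink:
    """One consumer -> substrate edge of the food web.

    ``k_s`` is the half-saturation density (g C m^-3) of the Monod term.
    ``pore_classes`` is the set of pore-class indices through which the
    consumer can reach this substrate; by default it is derived from the
    consumer's body-size class.
    """

    consumer: str
    substrate: str
    k_s: float
    pore_classes: tuple = ()

    def __post_init__(self):
        if self.consumer not in GUILDS:
            raise ValidationError(f"unknown consumer guild {self.consumer!r}")
        if self.substrate not in POOLS + EXTRA_SUBSTRATES:
            raise ValidationError(f"unknown substrate {self.substrate!r}")
        if not self.k_s > 0:
            raise ValidationError(f"K_s must be > 0 on link {self.consumer}->{self.substrate}")


@dataclass
class GuildParams:
    """Biology of one functional group.

    Rates are specific (g C per g C biomass per day).  ``f_faec`` is the
    fraction of consumed carbon egested as faeces, ``m_faec`` its sensitivity
    to substrate C:N (detritivores and engineers only).  ``p_m_cn`` and
    ``p_m_rec`` are the C:N and recalcitrance sensitivities of the growth
    rate (applied to litter/SOM consumption).  The temperature response is a
    Q10 curve between ``t_min`` and ``t_max`` with a plateau above ``t_opt``.
    """

    name: str
    g_max: float
    r: float
    d: float
    f_faec: float = 0.0
    m_faec: float = 0.0
    cn: float = 6.0
    p_m_cn: float = 0.0
    p_m_rec: float = 0.0
    t_min: float = 0.0
    t_opt: float = 20.0
    t_max: float = 35.0
    q10: float = 2.0
    size_class: str = "meso"

    def __post_init__(self):
        if not (self.t_min < self.t_opt < self.t_max):
            raise ValidationError(
                f"{self.name}: need t_min < t_opt < t_max, got "
                f"{self.t_min}, {self.t_opt}, {self.t_max}"
            )
        for attr in ("g_max", "r", "d"):
            if getattr(self, attr) < 0:
                raise ValidationError(f"{self.name}: rate {attr} must be >= 0")
        if not 0.0 <= self.f_faec <= 1.0:
            raise ValidationError(f"{self.name}: f_faec must be in [0,1]")
        if self.size_class not in SIZE_CLASS_ACCESS:
            raise ValidationError(f"{self.name}: unknown size class {self.size_class!r}")
        if self.cn <= 0:
            raise ValidationError(f"{self.name}: C:N must be > 0")

    @property
    def accessible_classes(self) -> tuple:
        """Pore-class indices this guild can enter."""
        if self.name == "engineers":
            return (1, 2, 3, 4)
        return SIZE_CLASS_ACCESS[self.size_class]


@dataclass
class LitterQuality:
    """Chemical quality of a dead organic pool: C:N ratio and recalcitrant fraction."""

    cn: float
    rec: float

    def __post_init__(self):
        if self.cn <= 0:
            raise ValidationError(f"C:N must be > 0, got {self.cn}")
        if not 0.0 <= self.rec <= 1.0:
            raise ValidationError(f"recalcitrant fraction must be in [0,1], got {self.rec}")


@dataclass
class SoilTexture:
    """Mineral-phase description of the (single) soil layer."""

    pct_sand: float
    pct_clay: float
    pct_som: float
    bulk_density: float  # D_b, g cm^-3
    ph: float
    layer_thickness: float = 0.9  # m
    mineral_density: float = 2.65  # D_m, g cm^-3
    som_density: float = 1.35  # D_SOM, g cm^-3

    def __post_init__(self):
        if not 0.0 <= self.pct_clay <= 100.0:
            raise ValidationError("clay percentage out of [0,100]")
        if not 0.0 <= self.pct_som <= 100.0:
            raise ValidationError("SOM percentage out of [0,100]")
        if self.layer_thickness <= 0:
            raise ValidationError("layer thickness must be > 0")
        # particle density check needs porosity helpers; done in init_state

    @property
    def f_clay(self) -> float:
        return self.pct_clay / 100.0


@dataclass
class ExternalInputs:
    """Boundary carbon inputs, daily rates in g C m^-3 day^-1.

    ``root_biomass`` (g C m^-3) is the fixed root boundary pool available to
    herbivores; it is replenished to this value every day.
    """

    litter_fall: float = 0.0
    root_litter: float = 0.0
    exudation: float = 0.0
    myc_allocation: float = 0.0
    root_biomass: float = 0.0

    def __post_init__(self):
        for f in dc_fields(self):
            if getattr(self, f.name) < 0:
                raise ValidationError(f"external input {f.name} must be >= 0")


@dataclass
class SiteConfig:
    """Complete site configuration for a run (see the packaged fixture YAML)."""

    texture: SoilTexture
    initial_pools: dict
    litter_quality: LitterQuality
    som_quality: LitterQuality
    inputs: ExternalInputs
    guilds: dict  # name -> GuildParams
    diet: list  # list[DietLink]
    # structural parameters
    f_pv: float = 0.5  # fraction of biopore volume adding to macroporosity
    pv_bmax: float = 50.0  # l m^-3
    ve_ratio: float = 0.05  # l per g C engineer
    burrow_lifespan_days: float = 3650.0
    k_ag: float = 2.0  # l per g C (aggregation porosity coefficient)
    c_ag: float = 10.0  # aggregation fraction coefficient
    pv_ag_cap: float = 20.0  # l m^-3, max extra aggregation porosity (2%)
    # hydrology
    i_max_mat: float | None = None  # mm day^-1; derived from texture if None
    i_max_mat_subsoil: float = 50.0  # mm day^-1
    fc_includes_meso: bool = False
    initial_water: str | float = "field_capacity"
    pv_text: dict | None = None  # optional explicit textural pore volumes, l m^-3
    # litter-fall / root-litter quality
    litterfall_quality: LitterQuality | None = None
    rootlitter_quality: LitterQuality | None = None
    # leaching
    f_dom: float = 0.02
    dom_return_rate: float = 0.05
    a_kd: float = 0.001226
    b_kd: float = 0.000212
    c_kd: float = 0.00374
    # bioturbation rates, g C per g C engineer per day
    bioturb_litter_rate: float = 0.01
    bioturb_som_rate: float = 0.05
    name: str = "site"
    latitude: float = 51.3

    def __post_init__(self):
        if self.litterfall_quality is None:
            self.litterfall_quality = LitterQuality(self.litter_quality.cn, self.litter_quality.rec)
        if self.rootlitter_quality is None:
            self.rootlitter_quality = LitterQuality(self.som_quality.cn, self.som_quality.rec)
        missing = [p for p in POOLS if p not in self.initial_pools]
        if missing:
            raise ConfigurationError(f"initial pool values missing for: {', '.join(missing)}")
        for p, v in self.initial_pools.items():
            if v < 0:
                raise ValidationError(f"initial pool {p!r} is negative")
        missing_g = [g for g in GUILDS if g not in self.guilds]
        if missing_g:
            raise ConfigurationError(f"guild parameters missing for: {', '.join(missing_g)}")
        if not self.diet:
            raise ConfigurationError("diet must be non-empty")
        if not 0.0 < self.f_pv <= 1.0:
            raise ValidationError("f_pv must be in (0,1]")

    @property
    def tpv_b(self) -> float:
        """Daily burrow turnover rate (1 / lifespan in days)."""
        return 1.0 / self.burrow_lifespan_days

    @property
    def k_d(self) -> float:
        """DOM adsorption coefficient K_D (m^3 per kg soil): a - b*pH + c*fClay."""
        return self.a_kd - self.b_kd * self.texture.ph + self.c_kd * self.texture.f_clay

    @property
    def soil_mass(self) -> float:
        """Dry soil mass per m^3 (kg)."""
        return self.texture.bulk_density * 1000.0

    def copy(self):
        import copy as _copy

        return _copy.deepcopy(self)


def init_state(config: SiteConfig):
    """Build the initial (PoolVector, PoreState, WaterState) for a run.

    Pools take the configured initial values; textural pore volumes come from
    the explicit table when given, otherwise from the pedotransfer helper; the
    initial water content is either the configured value (l m^-3) or the
    string ``"field_capacity"``.
    """
    from . import hydrology, porosity

    pools = PoolVector(**{p: float(config.initial_pools[p]) for p in POOLS})
    pools.validate()

    if config.pv_text is not None:
        missing = [c for c in PORE_CLASSES if c not in config.pv_text]
        if missing:
            raise ConfigurationError(f"pv_text missing classes: {', '.join(missing)}")
        pv_text = np.array([float(config.pv_text[c]) for c in PORE_CLASSES])
        if (pv_text < 0).any():
            raise ValidationError("textural pore volumes must be >= 0")
    else:
        d_s = porosity.particle_density(config.texture.pct_som)
        if config.texture.bulk_density >= d_s:
            raise ValidationError(
                f"bulk density {config.texture.bulk_density} must be below "
                f"particle density {d_s:.4f}"
            )
        p_pct = porosity.total_porosity_percent(d_s, config.texture.bulk_density)
        pv_text = porosity.texture_pore_volumes(
            p_pct, config.texture.pct_sand, config.texture.pct_clay
        )

    pore = porosity.PoreState.from_textural(
        pv_text,
        f_pv=config.f_pv,
        pv_bmax=config.pv_bmax,
        ve_ratio=config.ve_ratio,
        tpv_b=config.tpv_b,
        k_ag=config.k_ag,
        c_ag=config.c_ag,
        pv_ag_cap=config.pv_ag_cap,
    )
    # structural state consistent with the initial biology
    ag = porosity.aggregation_fraction(
        pools.fungi, pools.mycorrhiza, pools.som, c_ag=config.c_ag
    )
    pore = porosity.pore_size_distribution(ag, 0.0, pools.som, pore)

    i_max_mat = config.i_max_mat
    if i_max_mat is None:
        i_max_mat = hydrology.matrix_infiltration_capacity(config.texture.f_clay)

    if config.initial_water == "field_capacity":
        sw0 = hydrology.field_capacity(pore, include_meso=config.fc_includes_meso)
    else:
        sw0 = float(config.initial_water)
        if not 0.0 <= sw0 <= pore.pv_tot:
            raise ValidationError("initial water outside [0, total porosity]")
    water = hydrology.allocate_water_to_classes(sw0, pore)
    water.i_max_mat = i_max_mat
    water.i_max_mat_subsoil = config.i_max_mat_subsoil
    return pools, pore, water


def total_carbon(pools: PoolVector) -> float:
    """Conservation diagnostic: live + dead pools + tracked sinks - inputs.

    Constant over a simulation up to floating-point roundoff, because every
    carbon sink (CO2, leached DOM, bioturbation export) is a tracked
    cumulative term and every source accumulates in ``inputs_cum``.
    """
    return (
        float(pools.as_array().sum())
        + pools.co2_cum
        + pools.dom_leached_cum
        + pools.bioturb_export_cum
        - pools.inputs_cum
    )
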