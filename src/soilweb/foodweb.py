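"""Daily carbon fluxes of the soil food web.

Growth follows Monod kinetics over each consumer's accessible substrates,
with accessibility set by pore-size structure and per-class moisture.  Losses
are respiration (temperature dependent), constant-rate turnover (to SOM) and
predation.  Consumption of litter/SOM exceeds growth by the faeces fraction
(consumption = growth / (1 - f_faecEff)); consumption of live prey costs the
prey G*(1 + f_faec).  All fluxes are assembled in a :class:`FluxLedger`, and
a carbon-conserving limiter scales every outgoing flux of a pool that would
otherwise go negative within the daily Euler step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_state import (
    GUILDS,
    POOLS,
    GuildParams,
    LitterQuality,
    PoolVector,
    SiteConfig,
    ValidationError,
)
from .hydrology import WaterState
from .modifiers import (
    cn_modifier,
    litter_moisture,
    moisture_modifier_by_class,
    ph_gmax_engineers,
    ph_modifier_microbe,
    recalcitrance_modifier,
    respiration_temperature_factor,
    temperature_modifier,
)
from .porosity import MESO, MACRO, PoreState

__all__ = [
    "ROOTS",
    "FluxLedger",
    "available_fraction",
    "monod_growth",
    "respiration",
    "turnover",
    "predation_loss",
    "effective_faeces_fraction",
    "bioturbation",
    "pool_derivatives",
    "integrate",
    "update_pool_quality",
]

N_POOLS = len(POOLS)
LITTER = POOLS.index("litter")
SOM = POOLS.index("som")
DOM = POOLS.index("dom")
#: pseudo-pool index of the external root boundary pool
ROOTS = N_POOLS

#: cap on the effective faeces fraction; consumption = G/(1 - f_faecEff)
#: is singular at 1 (never binds with the shipped parameter table)
F_FAEC_MAX = 0.95


@dataclass
class FluxLedger:
    """All raw daily fluxes (g C m^-3 day^-1), one row per diet link.

    ``scales`` holds the per-source-pool limiter factors applied by
    :func:`integrate` (index :data:`ROOTS` is the root boundary pool); after
    integration the link arrays and resp/turn are already scaled.
    """

    consumers: np.ndarray  # (L,) guild index
    substrates: np.ndarray  # (L,) pool index, ROOTS for the root pool
    growth: np.ndarray  # (L,)
    cons: np.ndarray  # (L,) substrate depletion
    faeces: np.ndarray  # (L,) flux to SOM
    resp: np.ndarray  # (9,)
    turn: np.ndarray  # (9,)
    scales: np.ndarray = field(default_factory=lambda: np.ones(N_POOLS + 1))

    @property
    def r_tot(self) -> float:
        """Total respiration, g C m^-3 day^-1."""
        return float(self.resp.sum())

    def growth_of(self, guild_idx: int) -> float:
        return float(self.growth[self.consumers == guild_idx].sum())

    def predation_on(self, pool_idx: int) -> float:
        """Total consumption taken from a pool by its consumers."""
        return float(self.cons[self.substrates == pool_idx].sum())

    @property
    def faeces_total(self) -> float:
        return float(self.faeces.sum())

    def check_link_closure(self, rtol: float = 1e-9) -> bool:
        """Per-link identity: consumption = growth + faeces."""
        return np.allclose(self.cons, self.growth + self.faeces, rtol=rtol, atol=1e-12)


def available_fraction(
    consumer: GuildParams,
    substrate: str,
    pore: PoreState,
    water: WaterState | None = None,
    class_m: np.ndarray | None = None,
    substrate_params: GuildParams | None = None,
    pore_classes: tuple = (),
) -> float:
    """Fraction of a substrate pool reachable by a consumer, in [0, 1].

    Pore-resident substrates (SOM, live prey, roots) are taken as distributed
    over their domain of pore classes in proportion to pore volume; the
    consumer reaches the intersection of that domain with its own accessible
    classes, each class weighted by its moisture modifier.  Surface litter is
    outside the matrix and uses the microbial-habitat moisture modifier.
    """
    if class_m is None:
        if water is None:
            raise ValidationError("need either class_m or water")
        class_m = moisture_modifier_by_class(water, pore)
    acc = tuple(pore_classes) or consumer.accessible_classes
    if substrate == "litter":
        return litter_moisture(class_m, pore)
    if substrate == "som":
        domain = (0, 1, 2, 3, 4)
    elif substrate == "roots":
        domain = (MESO, MACRO)
    elif substrate in GUILDS:
        if substrate_params is None:
            raise ValidationError("substrate_params required for a prey guild")
        domain = substrate_params.accessible_classes
    else:
        raise ValidationError(f"unknown substrate {substrate!r}")
    den = float(pore.pv[list(domain)].sum())
    if den <= 0.0:
        return 0.0
    reach = [c for c in domain if c in acc]
    num = float(sum(pore.pv[c] * class_m[c] for c in reach))
    return min(1.0, num / den)


def monod_growth(b: float, substrates, g_max_effective: float) -> float:
    """Monod growth over a list of (S, f_a, K_s): additive across substrates.

    G = sum_n g_max_eff * (S*f_a / (K_s + S))_n * B.
    """
    if b < 0:
        raise ValidationError("biomass must be >= 0")
    g = 0.0
    for s, f_a, k_s in substrates:
        if s < 0:
            raise ValidationError("substrate must be >= 0")
        if s > 0.0:
            g += g_max_effective * (s * f_a / (k_s + s)) * b
    return g


def respiration(b: float, r: float, resp_t_factor: float) -> float:
    """R = r * temperature factor * B (g C m^-3 day^-1)."""
    if b < 0 or r < 0:
        raise ValidationError("inputs must be >= 0")
    return r * resp_t_factor * b


def turnover(b: float, d: float) -> float:
    """Constant-rate mortality D_t = d*B, routed to SOM."""
    if b < 0 or d < 0:
        raise ValidationError("inputs must be >= 0")
    return d * b


def predation_loss(g_pred_share: float, f_faec_pred: float):
    """Prey-side cost of predator growth G: returns (prey loss, faeces to SOM).

    The prey loses G*(1 + f_faec); the predator keeps G; G*f_faec is egested.
    """
    if g_pred_share < 0 or f_faec_pred < 0:
        raise ValidationError("inputs must be >= 0")
    return g_pred_share * (1.0 + f_faec_pred), g_pred_share * f_faec_pred


def effective_faeces_fraction(
    f_faec: float, m_faec: float, cn_substrate: float, cn_consumer: float
) -> float:
    """Faeces fraction increased on N-poor substrate (detritivores/engineers).

    f_faecEff = f_faec * (1 + m_faec*(CN_sub - CN_consumer)/CN_sub), clamped
    to [0, F_FAEC_MAX].
    """
    if cn_substrate <= 0 or cn_consumer <= 0:
        raise ValidationError("C:N ratios must be > 0")
    f_eff = f_faec + m_faec * ((cn_substrate - cn_consumer) / cn_substrate) * f_faec
    return min(max(f_eff, 0.0), F_FAEC_MAX)


def bioturbation(b_eng: float, rates, litter: float, som: float):
    """Litter and SOM exported from the layer by engineers (g C m^-3 day^-1).

    exports = rate * B_eng, capped at the available pool.  With a single soil
    layer this carbon leaves the modelled system.
    """
    rate_lit, rate_som = rates
    if min(b_eng, rate_lit, rate_som, litter, som) < 0:
        raise ValidationError("inputs must be >= 0")
    return min(rate_lit * b_eng, litter), min(rate_som * b_eng, som)


def _effective_g_max(g: GuildParams, ph: float, t: float) -> float:
    """g_max after temperature and pH; substrate-quality factors are per link."""
    m_t = temperature_modifier(t, g.t_min, g.t_opt, g.t_max, g.q10)
    if g.name == "engineers":
        return ph_gmax_engineers(g.g_max, ph) * m_t
    if g.name == "bacteria":
        return g.g_max * ph_modifier_microbe(ph, "bacteria") * m_t
    if g.name in ("fungi", "mycorrhiza"):
        return g.g_max * ph_modifier_microbe(ph, "fungi") * m_t
    return g.g_max * m_t


def pool_derivatives(
    pools: PoolVector,
    config: SiteConfig,
    pore: PoreState,
    water: WaterState,
    t_soil: float,
    litter_quality: LitterQuality | None = None,
    som_quality: LitterQuality | None = None,
):
    """Assemble all raw daily fluxes and the per-pool derivatives.

    Returns ``(deriv, ledger)`` where ``deriv`` is the unlimited dB/dt per
    pool (g C m^-3 day^-1, canonical order; DOM production and external
    inputs are handled by the engine) and ``ledger`` the raw
    :class:`FluxLedger`.  Raises on non-finite intermediates.
    """
    lq = litter_quality or config.litter_quality
    sq = som_quality or config.som_quality
    class_m = moisture_modifier_by_class(water, pore)
    lit_m = litter_moisture(class_m, pore)
    b = pools.as_array()
    ph = config.texture.ph

    links = config.diet
    n = len(links)
    consumers = np.empty(n, dtype=np.int64)
    substrates = np.empty(n, dtype=np.int64)
    growth = np.zeros(n)
    cons = np.zeros(n)
    faeces = np.zeros(n)

    g_eff = {name: _effective_g_max(config.guilds[name], ph, t_soil) for name in GUILDS}

    for i, link in enumerate(links):
        g = config.guilds[link.consumer]
        gi = GUILDS.index(link.consumer)
        consumers[i] = gi
        if link.substrate == "roots":
            si = ROOTS
            s = config.inputs.root_biomass
        else:
            si = POOLS.index(link.substrate)
            s = b[si]
        substrates[i] = si
        f_a = available_fraction(
            g,
            link.substrate,
            pore,
            class_m=class_m,
            substrate_params=config.guilds.get(link.substrate),
            pore_classes=link.pore_classes,
        )
        if link.substrate == "litter":
            m_q = cn_modifier(g.cn, lq.cn, g.p_m_cn) * recalcitrance_modifier(lq.rec, g.p_m_rec)
        elif link.substrate == "som":
            m_q = cn_modifier(g.cn, sq.cn, g.p_m_cn) * recalcitrance_modifier(sq.rec, g.p_m_rec)
        else:
            m_q = 1.0
        gl = monod_growth(b[gi], [(s, f_a, link.k_s)], g_eff[link.consumer] * m_q)
        growth[i] = gl
        if link.substrate in ("litter", "som"):
            q_cn = lq.cn if link.substrate == "litter" else sq.cn
            f_eff = effective_faeces_fraction(g.f_faec, g.m_faec, q_cn, g.cn)
            cons[i] = gl / (1.0 - f_eff)
            faeces[i] = cons[i] - gl
        else:
            loss, fae = predation_loss(gl, g.f_faec)
            cons[i] = loss
            faeces[i] = fae

    resp = np.zeros(9)
    turn = np.zeros(9)
    for gi, name in enumerate(GUILDS):
        g = config.guilds[name]
        f_r = respiration_temperature_factor(t_soil, g.t_opt, g.q10, g.t_min, g.t_max)
        resp[gi] = respiration(b[gi], g.r, f_r)
        turn[gi] = turnover(b[gi], g.d)

    ledger = FluxLedger(consumers, substrates, growth, cons, faeces, resp, turn)

    deriv = np.zeros(N_POOLS)
    for gi in range(9):
        deriv[gi] = (
            ledger.growth_of(gi) - resp[gi] - turn[gi] - ledger.predation_on(gi)
        )
    deriv[LITTER] = -ledger.predation_on(LITTER)
    deriv[SOM] = float(turn.sum()) + ledger.faeces_total - ledger.predation_on(SOM)
    if not np.isfinite(deriv).all():
        raise FloatingPointError(
            f"non-finite derivative; fluxes: growth={growth}, cons={cons}, resp={resp}"
        )
    return deriv, ledger


def integrate(pools: PoolVector, ledger: FluxLedger, config: SiteConfig, dt: float = 1.0):
    """Forward-Euler daily update with a carbon-conserving flux limiter.

    Every flux has a unique source pool; if a pool's total outgoing flux over
    ``dt`` exceeds its content, all its outgoing fluxes are scaled by
    available/required, so pools never go negative and the balance still
    closes.  External inputs (litter fall, root litter, mycorrhizal
    allocation, exudation) and DOM production from respiration are applied
    here; DOM leaching and bioturbation are separate engine steps.

    Returns the updated :class:`PoolVector`; ``ledger`` is scaled in place.
    """
    b = pools.as_array()
    avail = np.append(b, config.inputs.root_biomass)
    out = np.zeros(N_POOLS + 1)
    for i in range(len(ledger.cons)):
        out[ledger.substrates[i]] += ledger.cons[i]
    for gi in range(9):
        out[gi] += ledger.resp[gi] + ledger.turn[gi]

    scales = np.ones(N_POOLS + 1)
    need = out * dt
    mask = need > avail
    scales[mask] = np.where(need[mask] > 0.0, avail[mask] / need[mask], 0.0)
    ledger.scales = scales

    ledger.cons *= scales[ledger.substrates]
    ledger.growth *= scales[ledger.substrates]
    ledger.faeces *= scales[ledger.substrates]
    ledger.resp *= scales[:9]
    ledger.turn *= scales[:9]

    inp = config.inputs
    delta = np.zeros(N_POOLS)
    for i in range(len(ledger.cons)):
        si = ledger.substrates[i]
        if si < N_POOLS:
            delta[si] -= ledger.cons[i]
        delta[ledger.consumers[i]] += ledger.growth[i]
        delta[SOM] += ledger.faeces[i]
    for gi in range(9):
        delta[gi] -= ledger.resp[gi] + ledger.turn[gi]
        delta[SOM] += ledger.turn[gi]
    delta[LITTER] += inp.litter_fall
    delta[SOM] += inp.root_litter
    delta[GUILDS.index("mycorrhiza")] += inp.myc_allocation

    r_tot = ledger.r_tot
    dom_prod = config.f_dom * r_tot
    delta[DOM] += dom_prod + inp.exudation

    out_pools = pools.copy()
    new_b = b + dt * delta
    new_b[np.abs(new_b) < 1e-13] = np.maximum(new_b[np.abs(new_b) < 1e-13], 0.0)
    if (new_b < -1e-9).any():
        bad = [POOLS[i] for i in np.where(new_b < -1e-9)[0]]
        raise FloatingPointError(f"limiter failed, negative pools: {bad}")
    out_pools.set_pools(np.maximum(new_b, 0.0))
    out_pools.co2_cum += dt * r_tot * (1.0 - config.f_dom)
    root_cons = float(ledger.cons[ledger.substrates == ROOTS].sum())
    out_pools.inputs_cum += dt * (
        inp.litter_fall + inp.root_litter + inp.myc_allocation + inp.exudation + root_cons
    )
    return out_pools


def update_pool_quality(mass_retained: float, quality: LitterQuality, influxes) -> LitterQuality:
    """Mix pool quality with influxes, conserving nitrogen implicitly.

    ``influxes`` is an iterable of (mass g C, C:N, recalcitrant fraction).
    C:N mixes on a nitrogen-mass basis (harmonic in C:N); the recalcitrant
    fraction mixes as a carbon-mass-weighted mean.  Empty pools adopt the
    influx quality.
    """
    if mass_retained < 0:
        raise ValidationError("retained mass must be >= 0")
    c_tot = mass_retained
    n_tot = mass_retained / quality.cn
    rec_mass = mass_retained * quality.rec
    for mass, cn, rec in influxes:
        if mass < 0:
            raise ValidationError("influx mass must be >= 0")
        c_tot += mass
        n_tot += mass / cn
        rec_mass += mass * rec
    if c_tot <= 0.0:
        return LitterQuality(quality.cn, quality.rec)
    cn_new = c_tot / n_tot if n_tot > 0 else quality.cn
    return LitterQuality(cn_new, min(1.0, rec_mass / c_tot))
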