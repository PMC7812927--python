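"""The daily simulation loop.

Each day executes, in order: (a) pore-size distribution from yesterday's
biology, (b) the water balance and allocation of water to pore classes,
(c) DOM leaching with the draining water, (d/e) accessibility and growth
modifiers, (f/g) the pool differential equations integrated by forward Euler
with a conserving flux limiter, (h) litter/SOM quality updates, (i) engineer
effects (burrow volume, bioturbation exports) and (j) an optional structural
hook.  The forward model holds no randomness: a configuration and climate
series map deterministically to a daily trace.

Two execution paths produce the same numbers: :func:`daily_step` composes the
module operations one by one (the readable reference), while :func:`run`
defaults to a compiled kernel (~two orders of magnitude faster) used for
calibration and ensembles; their agreement is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import foodweb, hydrology, leaching, porosity
from .core_state import (
    GUILDS,
    PORE_CLASSES,
    POOLS,
    LitterQuality,
    PoolVector,
    SiteConfig,
    init_state,
)
from .foodweb import LITTER, ROOTS, SOM
from .porosity import MACRO

__all__ = ["ModelState", "SimulationResult", "TRACE_COLUMNS", "daily_step", "run"]

TRACE_COLUMNS = (
    ("day",)
    + POOLS
    + ("sw",)
    + tuple(f"pv_{c}" for c in PORE_CLASSES)
    + tuple(f"w_{c}" for c in PORE_CLASSES)
    + ("runoff_mm", "drainage_mm", "dom_leached", "r_tot")
)


@dataclass
class ModelState:
    """Full mutable state carried between days."""

    pools: PoolVector
    pore: porosity.PoreState
    water: hydrology.WaterState
    litter_quality: LitterQuality
    som_quality: LitterQuality
    day: int = 0

    @classmethod
    def from_config(cls, config: SiteConfig) -> "ModelState":
        pools, pore, water = init_state(config)
        lq = config.litter_quality
        sq = config.som_quality
        return cls(
            pools=pools,
            pore=pore,
            water=water,
            litter_quality=LitterQuality(lq.cn, lq.rec),
            som_quality=LitterQuality(sq.cn, sq.rec),
        )


@dataclass
class SimulationResult:
    """Daily trace plus cumulative flux attribution for one run."""

    trace: np.ndarray  # (n_days, len(TRACE_COLUMNS))
    final_pools: PoolVector
    resp_cum: np.ndarray  # (9,) cumulative respiration per guild
    cons_cum: np.ndarray  # (L,) cumulative consumption per diet link
    link_meta: list  # [(consumer, substrate), ...]
    bioturb_litter_cum: float
    bioturb_som_cum: float
    config: SiteConfig

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.trace, columns=list(TRACE_COLUMNS))

    def pool(self, name: str) -> np.ndarray:
        return self.trace[:, TRACE_COLUMNS.index(name)]

    @property
    def n_days(self) -> int:
        return self.trace.shape[0]

    def mean_swc(self) -> float:
        return float(self.pool("sw").mean())

    def consumption(self, consumer: str, substrate: str) -> float:
        """Cumulative consumption over the run for one diet link (g C m^-3)."""
        for i, (c, s) in enumerate(self.link_meta):
            if c == consumer and s == substrate:
                return float(self.cons_cum[i])
        return 0.0


def daily_step(state: ModelState, climate_day, config: SiteConfig, structural_hook=None):
    """Advance the model one day (the readable reference path).

    ``climate_day`` is ``(p_mm, e_mm, t_celsius)``.  Returns the new
    :class:`ModelState` and a dict of per-day outputs (the trace row plus the
    scaled flux ledger and bioturbation exports).  Sub-step failures raise
    with the step label and day index attached.
    """
    p_mm, e_mm, t_soil = climate_day
    pools = state.pools.copy()
    step = "a:porosity"
    try:
        # (a) pore size distribution from yesterday's biology and burrows
        ag = porosity.aggregation_fraction(
            pools.fungi, pools.mycorrhiza, pools.som, c_ag=config.c_ag
        )
        pore = porosity.pore_size_distribution(ag, state.pore.pv_b, pools.som, state.pore)

        # (b) water balance and per-class allocation
        step = "b:hydrology"
        water, runoff_mm, drain_mm = hydrology.water_step(
            state.water,
            pore,
            p_mm,
            e_mm,
            config.texture.layer_thickness,
            fc_includes_meso=config.fc_includes_meso,
        )

        # (c) DOM leaching with the draining water, then slow re-stabilization
        step = "c:leaching"
        drain_lm3 = drain_mm / config.texture.layer_thickness
        leach = leaching.dom_leaching(
            pools.dom, config.k_d, config.soil_mass, water.sw, drain_lm3
        )
        pools.dom -= leach
        pools.dom_leached_cum += leach
        ret = config.dom_return_rate * pools.dom
        pools.dom -= ret
        pools.som += ret

        # (d)-(f) accessibility, modifiers, fluxes
        step = "d-f:fluxes"
        _, ledger = foodweb.pool_derivatives(
            pools, config, pore, water, t_soil, state.litter_quality, state.som_quality
        )

        # (g) integrate with the conserving limiter
        step = "g:integrate"
        pools = foodweb.integrate(pools, ledger, config)

        # (h) update litter and SOM quality from today's influxes
        step = "h:quality"
        inp = config.inputs
        lq, sq = state.litter_quality, state.som_quality
        retained_lit = max(0.0, pools.litter - inp.litter_fall)
        new_lq = foodweb.update_pool_quality(
            retained_lit,
            lq,
            [(inp.litter_fall, config.litterfall_quality.cn, config.litterfall_quality.rec)],
        )
        som_influx = [
            (inp.root_litter, config.rootlitter_quality.cn, config.rootlitter_quality.rec)
        ]
        for i in range(len(ledger.cons)):
            if ledger.faeces[i] > 0.0:
                si = ledger.substrates[i]
                if si == LITTER:
                    som_influx.append((ledger.faeces[i], lq.cn, lq.rec))
                elif si == SOM:
                    som_influx.append((ledger.faeces[i], sq.cn, sq.rec))
                elif si == ROOTS:
                    som_influx.append(
                        (ledger.faeces[i], config.rootlitter_quality.cn, 0.0)
                    )
                else:
                    som_influx.append((ledger.faeces[i], config.guilds[GUILDS[si]].cn, 0.0))
        for gi in range(9):
            if ledger.turn[gi] > 0.0:
                som_influx.append((ledger.turn[gi], config.guilds[GUILDS[gi]].cn, 0.0))
        influx_mass = sum(m for m, _, _ in som_influx)
        retained_som = max(0.0, pools.som - influx_mass)
        new_sq = foodweb.update_pool_quality(retained_som, sq, som_influx)

        # (i) engineering: burrows then bioturbation exports
        step = "i:engineers"
        pv_b = porosity.burrow_volume_update(
            pore.pv_b,
            pools.engineers,
            pore.pv[MACRO],
            pore.pv_text[MACRO],
            pv_bmax=config.pv_bmax,
            ve_ratio=config.ve_ratio,
            tpv_b=config.tpv_b,
        )
        pore.pv_b = pv_b
        b_lit, b_som = foodweb.bioturbation(
            pools.engineers,
            (config.bioturb_litter_rate, config.bioturb_som_rate),
            pools.litter,
            pools.som,
        )
        pools.litter -= b_lit
        pools.som -= b_som
        pools.bioturb_export_cum += b_lit + b_som

        # (j) structural hook (weather/management perturbations), default none
        step = "j:hook"
        if structural_hook is not None:
            structural_hook(pools, pore, water, config, state.day)
    except Exception as exc:
        raise type(exc)(f"day {state.day}, step {step}: {exc}") from exc

    new_state = ModelState(
        pools=pools,
        pore=pore,
        water=water,
        litter_quality=new_lq,
        som_quality=new_sq,
        day=state.day + 1,
    )
    row = np.empty(len(TRACE_COLUMNS))
    row[0] = state.day
    row[1:13] = pools.as_array()
    row[13] = water.sw
    row[14:19] = pore.pv
    row[19:24] = water.w
    row[24] = runoff_mm
    row[25] = drain_mm
    row[26] = leach
    row[27] = ledger.r_tot
    extras = {"ledger": ledger, "bioturb": (b_lit, b_som), "row": row}
    return new_state, extras


def _run_python(config: SiteConfig, climate, n_days: int) -> SimulationResult:
    state = ModelState.from_config(config)
    n_links = len(config.diet)
    trace = np.empty((n_days, len(TRACE_COLUMNS)))
    resp_cum = np.zeros(9)
    cons_cum = np.zeros(n_links)
    b_lit_cum = 0.0
    b_som_cum = 0.0
    for i in range(n_days):
        state, extras = daily_step(
            state, (climate.p[i], climate.e[i], climate.t[i]), config
        )
        trace[i] = extras["row"]
        resp_cum += extras["ledger"].resp
        cons_cum += extras["ledger"].cons
        b_lit_cum += extras["bioturb"][0]
        b_som_cum += extras["bioturb"][1]
    return SimulationResult(
        trace=trace,
        final_pools=state.pools,
        resp_cum=resp_cum,
        cons_cum=cons_cum,
        link_meta=[(l.consumer, l.substrate) for l in config.diet],
        bioturb_litter_cum=b_lit_cum,
        bioturb_som_cum=b_som_cum,
        config=config,
    )


def run(config: SiteConfig, climate, n_days: int | None = None, fast: bool = True) -> SimulationResult:
    """Run the model for ``n_days`` (default: the whole climate series).

    Deterministic given the configuration; ``fast=False`` selects the
    pure-Python reference path.
    """
    if n_days is None:
        n_days = len(climate)
    if n_days > len(climate):
        raise ValueError(
            f"climate series has {len(climate)} days, {n_days} requested"
        )
    if fast:
        from ._kernel import run_compiled

        return run_compiled(config, climate, n_days)
    return _run_python(config, climate, n_days)
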