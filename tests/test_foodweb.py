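"""Food-web fluxes: Monod growth, losses, faeces routing, quality mixing."""

import numpy as np
import pytest

import soilweb as sw
from soilweb.core_state import GuildParams, LitterQuality
from soilweb.engine import ModelState, daily_step, run
from soilweb.foodweb import (
    available_fraction,
    bioturbation,
    effective_faeces_fraction,
    monod_growth,
    predation_loss,
    respiration,
    turnover,
    update_pool_quality,
)
from soilweb.hydrology import allocate_water_to_classes
from soilweb.porosity import PoreState


class TestMonod:
    def test_half_saturation(self):
        assert monod_growth(10.0, [(5.0, 1.0, 5.0)], 0.4) == pytest.approx(0.5 * 0.4 * 10.0)

    def test_no_substrate_no_growth(self):
        assert monod_growth(10.0, [(0.0, 1.0, 5.0)], 0.4) == 0.0

    def test_additive_over_substrates(self):
        one = monod_growth(10.0, [(5.0, 0.5, 5.0)], 0.4)
        two = monod_growth(10.0, [(5.0, 0.5, 5.0)] * 2, 0.4)
        assert two == pytest.approx(2.0 * one)


class TestLossTerms:
    def test_respiration_product(self):
        assert respiration(100.0, 0.01, 2.0) == pytest.approx(2.0)
        assert respiration(0.0, 0.01, 2.0) == 0.0

    def test_turnover_product(self):
        assert turnover(10.0, 0.01) == pytest.approx(0.1)
        assert turnover(10.0, 0.0) == 0.0

    def test_predation_split(self):
        loss, faeces = predation_loss(1.0, 0.2)
        assert loss == pytest.approx(1.2)
        assert faeces == pytest.approx(0.2)
        assert predation_loss(1.0, 0.0) == (1.0, 0.0)


class TestFaeces:
    def test_effective_fraction_nitrogen_poor_substrate(self):
        assert effective_faeces_fraction(0.4, 1.0, 30.0, 6.0) == pytest.approx(0.72)

    def test_identity_cases(self):
        assert effective_faeces_fraction(0.4, 0.0, 30.0, 6.0) == 0.4
        assert effective_faeces_fraction(0.4, 1.0, 6.0, 6.0) == 0.4


class TestBioturbation:
    def test_exports_scale_with_biomass_and_cap(self):
        assert bioturbation(2.0, (0.1, 0.05), 100.0, 100.0) == (
            pytest.approx(0.2),
            pytest.approx(0.1),
        )
        assert bioturbation(1e6, (0.1, 0.05), 3.0, 100.0)[0] == 3.0
        assert bioturbation(0.0, (0.1, 0.05), 100.0, 100.0) == (0.0, 0.0)


class TestAvailableFraction:
    def _pore(self):
        return PoreState.from_textural(np.array([30.0, 50, 100, 200, 40]))

    def test_engineers_reach_everything_but_inaccessible(self, brasschaat):
        pore = self._pore()
        m = np.ones(5)
        eng = brasschaat.guilds["engineers"]
        fa = available_fraction(eng, "som", pore, class_m=m)
        assert fa == pytest.approx((50 + 100 + 200 + 40) / 420.0)

    def test_unreachable_substrate(self, brasschaat):
        pore = self._pore()
        bact = brasschaat.guilds["bacteria"]
        # roots sit in meso/macro pores; restrict the consumer elsewhere
        fa = available_fraction(bact, "roots", pore, class_m=np.ones(5), pore_classes=(1, 2))
        assert fa == 0.0

    def test_optimally_wet_gives_volume_fraction(self, brasschaat):
        pore = self._pore()
        det = brasschaat.guilds["detritivores"]  # meso fauna: classes 3, 4
        fa = available_fraction(det, "som", pore, class_m=np.ones(5))
        assert fa == pytest.approx(240.0 / 420.0)


class TestPoolDerivatives:
    def _state_and_step(self, cfg, t=20.0):
        state = ModelState.from_config(cfg)
        return daily_step(state, (0.0, 0.0, t), cfg)

    def test_zero_growth_is_pure_decay(self, brasschaat):
        from soilweb.core_state import ExternalInputs

        cfg = brasschaat.copy()
        cfg.inputs = ExternalInputs()
        for g in sw.GUILDS:
            cfg.guilds[g].g_max = 0.0
        state, extras = self._state_and_step(cfg)
        led = extras["ledger"]
        assert led.growth.max() == 0.0
        b0 = sw.init_state(cfg)[0]
        for gi, name in enumerate(sw.GUILDS):
            g = cfg.guilds[name]
            f_r = 2.0 ** ((20.0 - g.t_opt) / 10.0)
            expected = getattr(b0, name) * (1.0 - g.r * f_r - g.d)
            assert getattr(state.pools, name) == pytest.approx(expected, rel=1e-12)

    def test_microbes_produce_no_faeces(self, brasschaat):
        _, extras = self._state_and_step(brasschaat)
        led = extras["ledger"]
        for i, (consumer, _) in enumerate(
            (l.consumer, l.substrate) for l in brasschaat.diet
        ):
            if consumer in ("bacteria", "fungi", "mycorrhiza"):
                assert led.faeces[i] == 0.0
                assert led.cons[i] == pytest.approx(led.growth[i])

    def test_link_closure_every_link(self, brasschaat):
        _, extras = self._state_and_step(brasschaat)
        assert extras["ledger"].check_link_closure()

    def test_single_link_matches_scalar_oracle(self, brasschaat):
        """One consumer, one substrate, constant forcing: the engine reduces
        to a scalar Monod-Euler recurrence."""
        cfg = brasschaat.copy()
        cfg.initial_pools = {p: 0.0 for p in sw.POOLS}
        cfg.initial_pools["bacteria"] = 15.1
        cfg.initial_pools["som"] = 11470.0
        g = cfg.guilds["bacteria"]
        g.p_m_cn = 0.0
        g.p_m_rec = 0.0
        from soilweb.core_state import DietLink, ExternalInputs

        cfg.diet = [DietLink("bacteria", "som", k_s=22940.0)]
        cfg.inputs = ExternalInputs()
        cfg.f_dom = 0.0
        cfg.dom_return_rate = 0.0
        cfg.bioturb_som_rate = 0.0
        n = 120
        climate = sw.ClimateSeries(
            np.datetime64("2000-01-01") + np.arange(n),
            np.zeros(n), np.zeros(n), np.full(n, 20.0),
        )
        res = run(cfg, climate, n, fast=False)
        # oracle: accessibility is constant (no rain, no structural change)
        pools0, pore, water = sw.init_state(cfg)
        from soilweb.modifiers import moisture_modifier_by_class

        class_m = moisture_modifier_by_class(water, pore)
        fa = available_fraction(g, "som", pore, class_m=class_m)
        m_t = 2.0 ** ((20.0 - g.t_opt) / 10.0)  # below the optimum
        f_r = m_t
        b, s = 15.1, 11470.0
        for _ in range(n):
            growth = g.g_max * m_t * (s * fa / (22940.0 + s)) * b
            db = growth - g.r * f_r * b - g.d * b
            s += g.d * b - growth
            b += db
        assert res.final_pools.bacteria == pytest.approx(b, rel=1e-9)
        assert res.final_pools.som == pytest.approx(s, rel=1e-9)

    def test_trophic_cascade_of_predator_removal(self, brasschaat, climate_1y):
        """Predator exclusion releases microbivores and depresses fungi."""
        basal = run(brasschaat, climate_1y, 366)
        cfg = brasschaat.copy()
        cfg.initial_pools["predators"] = 0.0
        nopred = run(cfg, climate_1y, 366)
        microbiv = lambda r: (r.pool("bacterivores") + r.pool("fungivores")).mean()
        assert microbiv(nopred) >= microbiv(basal)
        assert nopred.pool("fungi").mean() <= basal.pool("fungi").mean()


class TestPoolQuality:
    def test_no_influx_unchanged(self):
        q = update_pool_quality(10.0, LitterQuality(30.0, 0.5), [])
        assert (q.cn, q.rec) == (30.0, 0.5)

    def test_equal_mass_cn_mixes_harmonically(self):
        q = update_pool_quality(5.0, LitterQuality(20.0, 0.0), [(5.0, 60.0, 0.0)])
        assert q.cn == pytest.approx(30.0)  # N-mass conserving, not arithmetic 40

    def test_rec_mixes_by_carbon_mass(self):
        q = update_pool_quality(5.0, LitterQuality(30.0, 0.5), [(5.0, 30.0, 0.0)])
        assert q.rec == pytest.approx(0.25)
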