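"""Particle density, porosity arithmetic, aggregation and burrow dynamics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from soilweb.core_state import ValidationError
from soilweb.porosity import (
    PoreState,
    aggregation_fraction,
    aggregation_porosity,
    burrow_volume_update,
    particle_density,
    pore_size_distribution,
    total_porosity_percent,
)


@pytest.mark.parametrize(
    "pct_som, expected",
    [
        (0.0, 2.65),  # pure mineral limit
        (100.0, 1.35),  # pure organic limit
        (3.0, 100.0 / (3.0 / 1.35 + 97.0 / 2.65)),  # ~2.5756
    ],
)
def test_particle_density(pct_som, expected):
    assert particle_density(pct_som) == pytest.approx(expected, rel=1e-12)


def test_particle_density_range_checked():
    with pytest.raises(ValidationError):
        particle_density(120.0)


class TestTotalPorosity:
    def test_half_bulk_density_gives_fifty_percent(self):
        assert total_porosity_percent(2.6, 1.3) == pytest.approx(50.0)

    def test_sandy_topsoil_value(self):
        d_s = particle_density(3.0)
        assert total_porosity_percent(d_s, 1.4) == pytest.approx(45.644, abs=5e-3)

    def test_vanishing_bulk_density_limit(self):
        assert total_porosity_percent(2.65, 1e-9) == pytest.approx(100.0, abs=1e-6)

    def test_denser_than_particles_rejected(self):
        with pytest.raises(ValidationError):
            total_porosity_percent(2.0, 2.5)


class TestAggregation:
    def test_no_fungi_no_aggregation(self):
        assert aggregation_fraction(0.0, 0.0, 11470.0) == 0.0

    def test_clamped_at_one(self):
        assert aggregation_fraction(2000.0, 0.0, 11470.0) == 1.0

    def test_fixture_scale_value(self):
        assert aggregation_fraction(50.0, 50.0, 11470.0) == pytest.approx(
            10.0 * 100.0 / 11470.0
        )

    def test_empty_som_degenerate_case(self):
        assert aggregation_fraction(10.0, 10.0, 0.0) == 0.0

    def test_porosity_zero_and_uncapped_and_capped(self):
        assert aggregation_porosity(0.0, 11470.0) == 0.0
        assert aggregation_porosity(0.0005, 11470.0) == pytest.approx(11.47)
        assert aggregation_porosity(0.0872, 11470.0) == 20.0  # cap binds


class TestBurrows:
    def test_no_engineers_no_relict_burrows(self):
        assert burrow_volume_update(0.0, 0.0, 40.0, 40.0) == 0.0

    def test_digging_clamped_at_maximum(self):
        assert burrow_volume_update(0.0, 1e6, 40.0, 40.0, pv_bmax=50.0) == 50.0

    def test_geometric_decay_with_ten_year_lifespan(self):
        pv_b = burrow_volume_update(10.0, 0.0, 50.0, 40.0)
        assert pv_b == pytest.approx(10.0 * (1.0 - 1.0 / 3650.0))
        # decaying daily for one lifespan leaves ~1/e of the volume
        v = 10.0
        for _ in range(3650):
            v = burrow_volume_update(v, 0.0, 40.0 + v, 40.0)
        assert v == pytest.approx(10.0 * np.exp(-1.0), rel=5e-3)


def _pore(textural, **kw):
    return PoreState.from_textural(np.asarray(textural, dtype=float), **kw)


class TestPoreSizeDistribution:
    def test_identity_without_biology(self):
        pore = _pore([30, 50, 100, 200, 40])
        out = pore_size_distribution(0.0, 0.0, 11470.0, pore)
        np.testing.assert_allclose(out.pv, pore.pv_text)

    def test_full_macropore_share(self):
        pore = _pore([30, 50, 100, 200, 40], f_pv=1.0)
        out = pore_size_distribution(0.0, 10.0, 0.0, pore)
        assert out.pv[3] == pytest.approx(200.0)  # mesopores untouched
        assert out.pv_tot == pytest.approx(pore.pv_text.sum() + 10.0)

    def test_mesopore_conversion_arithmetic(self):
        pore = _pore([30, 50, 100, 100, 40])
        out = pore_size_distribution(0.1, 0.0, 0.0, pore)  # no SOM: pure conversion
        assert out.pv[2] == pytest.approx(100.0 + 2.5)
        assert out.pv[1] == pytest.approx(50.0 + 2.5)
        assert out.pv[3] == pytest.approx(100.0 - 5.0)

    def test_negative_mesopores_clamped_with_warning(self):
        pore = _pore([30, 50, 100, 3, 40], f_pv=0.5)
        with pytest.warns(RuntimeWarning):
            out = pore_size_distribution(0.0, 20.0, 0.0, pore)
        assert out.pv[3] == 0.0
        assert out.clamped_deficit > 0.0

    @given(
        ag=st.floats(0.0, 1.0),
        pv_b=st.floats(0.0, 50.0),
        b_som=st.floats(0.0, 20000.0),
    )
    def test_total_identity_when_unclamped(self, ag, pv_b, b_som):
        """PV_tot = PV_text + PV_Ag + f_pv*PV_B whenever nothing was clamped."""
        pore = _pore([30, 50, 100, 200, 40], f_pv=0.5)
        out = pore_size_distribution(ag, pv_b, b_som, pore)
        if out.clamped_deficit == 0.0:
            expected = pore.pv_text.sum() + out.pv_ag + pore.f_pv * pv_b
            assert out.pv_tot == pytest.approx(expected, rel=1e-12)

    @given(ag1=st.floats(0.0, 1.0), ag2=st.floats(0.0, 1.0))
    def test_monotonic_in_aggregation(self, ag1, ag2):
        """More aggregation never shrinks micro/bacterial pores or grows mesopores."""
        lo, hi = sorted((ag1, ag2))
        pore = _pore([30, 50, 100, 200, 40])
        a = pore_size_distribution(lo, 0.0, 5000.0, pore)
        b = pore_size_distribution(hi, 0.0, 5000.0, pore)
        assert b.pv[2] >= a.pv[2] - 1e-12
        assert b.pv[1] >= a.pv[1] - 1e-12
        assert b.pv[3] <= a.pv[3] + 1e-12

    def test_engineer_free_macropores_stay_textural(self, zero_biology, climate_1y):
        from soilweb.engine import run

        res = run(zero_biology, climate_1y, 150, fast=False)
        pores, pore0, _ = __import__("soilweb").init_state(zero_biology)
        np.testing.assert_allclose(res.trace[:, 18], pore0.pv_text[4])
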