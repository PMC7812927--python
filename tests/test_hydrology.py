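"""Water balance: partition, drainage, smallest-first allocation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from soilweb.core_state import ValidationError
from soilweb.hydrology import (
    WaterState,
    allocate_water_to_classes,
    drainage,
    field_capacity,
    macropore_capacity,
    net_precipitation,
    partition_water,
    water_step,
)
from soilweb.porosity import PoreState


def _pore(vals):
    return PoreState.from_textural(np.asarray(vals, dtype=float))


class TestNetPrecipitation:
    @pytest.mark.parametrize("p,e,expected", [(5, 2, 3), (0, 3, -3), (4, 4, 0)])
    def test_examples(self, p, e, expected):
        assert net_precipitation(p, e) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            net_precipitation(-1, 0)


class TestMacroporeCapacity:
    def test_no_macropores_passes_subsoil_capacity(self):
        assert macropore_capacity(0.0, 10.0) == 10.0

    def test_sum_with_volume_converted_to_mm(self):
        assert macropore_capacity(20.0, 10.0, thickness=1.0) == 30.0

    def test_no_route_at_all(self):
        assert macropore_capacity(0.0, 0.0) == 0.0


class TestPartition:
    def test_runoff_above_both_capacities(self):
        runoff, fill, bypass = partition_water(50, 10, 20, 0.0, 1000, 0)
        assert runoff == 20
        assert runoff + fill + bypass == pytest.approx(50)

    def test_zero_net_precipitation(self):
        assert partition_water(0, 10, 20, 0.1, 1000, 0) == (0.0, 0.0, 0.0)

    def test_saturated_soil_all_bypasses(self):
        runoff, fill, bypass = partition_water(5, 10, 20, 0.1, 400, 400)
        assert fill == 0.0
        assert bypass == pytest.approx(5 - runoff)

    @given(
        p=st.floats(0.0, 200.0),
        sw=st.floats(0.0, 400.0),
        pv_macro_a=st.floats(0.0, 50.0),
        pv_macro_b=st.floats(0.0, 50.0),
    )
    def test_more_macropores_never_more_runoff(self, p, sw, pv_macro_a, pv_macro_b):
        lo, hi = sorted((pv_macro_a, pv_macro_b))
        r = []
        for pv_m in (lo, hi):
            i_max_por = macropore_capacity(pv_m, 10.0)
            r.append(partition_water(p, 10.0, i_max_por, min(1.0, pv_m / 1000), 400, sw)[0])
        assert r[1] <= r[0] + 1e-12

    @given(p=st.floats(0.0, 300.0), sw=st.floats(0.0, 430.0))
    def test_partition_identity(self, p, sw):
        runoff, fill, bypass = partition_water(p, 30.0, 60.0, 0.05, 430.0, sw)
        assert runoff + fill + bypass == pytest.approx(max(p, 0.0), abs=1e-9)
        assert min(runoff, fill, bypass) >= 0.0


class TestDrainage:
    def test_small_rain_dry_soil_only_macropore_share(self):
        sa = 0.05
        d = drainage(4.0, sa, pv_tot=430, sw=100, i_max_mat=30, fc=200, i_max_por=60)
        assert d == pytest.approx(4.0 * sa)

    def test_bucket_at_capacity_spills_all_matrix_inflow(self):
        d = drainage(10.0, 0.0, pv_tot=430, sw=200, i_max_mat=30, fc=200, i_max_por=60)
        assert d == pytest.approx(10.0)

    def test_no_rain_no_drainage(self):
        assert drainage(0.0, 0.1, 430, 100, 30, 200) == 0.0

    def test_literal_formula_available_for_comparison(self):
        lit = drainage(10.0, 0.2, 430, 100, 30, 200, literal=True)
        assert lit == pytest.approx(10.0 * 0.2 + 10.0 - 8.0)


class TestAllocation:
    def test_exact_class_boundary(self):
        pore = _pore([30, 50, 100, 200, 40])
        ws = allocate_water_to_classes(80.0, pore)
        np.testing.assert_allclose(ws.w, [30, 50, 0, 0, 0])
        assert ws.partial_class == 2  # next class is the (empty) partial one

    def test_saturated(self):
        pore = _pore([30, 50, 100, 200, 40])
        ws = allocate_water_to_classes(420.0, pore)
        np.testing.assert_allclose(ws.w, pore.pv)
        assert ws.partial_class is None

    def test_half_filled_class(self):
        pore = _pore([30, 50, 100, 200, 40])
        ws = allocate_water_to_classes(30 + 25.0, pore)
        assert ws.w[1] == pytest.approx(25.0)
        assert ws.partial_class == 1

    def test_overfull_clipped_with_warning(self):
        pore = _pore([30, 50, 100, 200, 40])
        with pytest.warns(RuntimeWarning):
            ws = allocate_water_to_classes(500.0, pore)
        assert ws.sw == pytest.approx(420.0)

    @given(
        sw_frac=st.floats(0.0, 1.0),
        pv=st.lists(st.floats(0.0, 200.0), min_size=5, max_size=5),
    )
    def test_matches_brute_force_smallest_first(self, sw_frac, pv):
        """Greedy allocation equals the cumulative-sum oracle on random states."""
        pore = _pore(pv)
        sw = sw_frac * pore.pv_tot
        ws = allocate_water_to_classes(sw, pore)
        cum = np.concatenate([[0.0], np.cumsum(pore.pv)])
        expected = np.clip(sw - cum[:-1], 0.0, pore.pv)
        np.testing.assert_allclose(ws.w, expected, atol=1e-9)
        assert ws.w.sum() == pytest.approx(sw, abs=1e-9)
        # at most one class strictly partial
        partial = [(0 < w < v) for w, v in zip(ws.w, pore.pv)]
        assert sum(partial) <= 1


class TestWaterStep:
    def test_daily_balance_closes(self):
        pore = _pore([30, 50, 100, 200, 40])
        ws = allocate_water_to_classes(150.0, pore)
        ws.i_max_mat = 30.0
        thickness = 0.9
        for p, e in [(12.0, 1.0), (0.0, 3.0), (60.0, 2.0)]:
            new, runoff, drain = water_step(ws, pore, p, e, thickness)
            p_net = p - e
            if p_net > 0:
                infil = p_net - runoff
                delta = (new.sw - ws.sw) * thickness
                assert infil == pytest.approx(delta + drain, abs=1e-9)
            ws = new

    def test_et_draws_down_to_wilting_point(self):
        pore = _pore([30, 50, 100, 200, 40])
        ws = allocate_water_to_classes(35.0, pore)
        for _ in range(60):
            ws, _, _ = water_step(ws, pore, 0.0, 5.0, 1.0)
        assert ws.sw == pytest.approx(pore.pv[0])  # water held in inaccessible pores

    def test_field_capacity_modes(self):
        pore = _pore([30, 50, 100, 200, 40])
        assert field_capacity(pore) == 180.0
        assert field_capacity(pore, include_meso=True) == 380.0
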