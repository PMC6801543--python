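"""USLE factors, erosion, sediment load, stream velocity and the
sedimentation index."""

import numpy as np
import pandas as pd
import pytest

from pestfate.sedimentation import (cover_factor_C, erodibility_K,
                                    sediment_load, sedimentation_index,
                                    slope_factor_S, stream_velocity,
                                    textural_factor_M, usle_erosion)
from pestfate.terrain import (d8_flow, delineate_watersheds, fill_pits)

from conftest import make_grid


class TestTexturalFactor:
    def test_standard_dialect_hand_value(self):
        # mvfs = 0.2·40 = 8; (30 + 8)·(100 − 20) = 3040
        assert textural_factor_M(30, 40, 20) == pytest.approx(3040.0)

    def test_pure_clay_gives_zero(self):
        assert textural_factor_M(0, 0, 100) == 0.0

    def test_as_printed_dialect(self):
        # 30 + 8·(100 − 20) = 670
        assert textural_factor_M(30, 40, 20, dialect="as_printed") == \
            pytest.approx(670.0)

    def test_negative_fraction_errors(self):
        with pytest.raises(ValueError):
            textural_factor_M(-1, 40, 20)


class TestErodibility:
    def test_nomograph_hand_value(self):
        assert erodibility_K(3040, 2, 2, 3) == pytest.approx(0.0258, abs=5e-4)

    def test_all_terms_vanish(self):
        assert erodibility_K(0, 12, 2, 3) == 0.0

    def test_monotone_decreasing_in_organic_matter(self):
        ks = [erodibility_K(3040, om, 2, 3) for om in np.linspace(0, 12, 7)]
        assert all(b <= a for a, b in zip(ks, ks[1:]))

    def test_floored_at_zero(self):
        assert erodibility_K(0, 12, 1, 1) == 0.0


class TestSlopeFactor:
    def test_flat(self):
        assert slope_factor_S(0.0) == pytest.approx(0.03)

    def test_below_breakpoint(self):
        assert slope_factor_S(5.0) == pytest.approx(
            10.8 * np.sin(np.radians(5)) + 0.03)
        assert slope_factor_S(5.0) == pytest.approx(0.971, abs=5e-4)

    def test_above_breakpoint(self):
        theta = np.degrees(np.arctan(0.2))  # 20 % slope
        assert slope_factor_S(theta) == pytest.approx(2.795, abs=5e-4)

    def test_branch_jump_below_one_hundredth(self):
        theta = np.degrees(np.arctan(0.09))
        low = 10.8 * np.sin(np.radians(theta)) + 0.03
        high = 16.8 * np.sin(np.radians(theta)) - 0.5
        assert abs(high - low) < 0.01

    def test_over_vertical_errors(self):
        with pytest.raises(ValueError):
            slope_factor_S(91.0)


class TestErosion:
    def test_cover_factor_complement(self):
        out = cover_factor_C(make_grid([0.0, 0.25, 1.0]))
        np.testing.assert_allclose(out.values[0], [1.0, 0.75, 0.0])

    def test_product_hand_value(self):
        E = usle_erosion(make_grid([[2000.0]]), make_grid([[0.0258]]),
                         make_grid([[0.5]]), make_grid([[0.971]]))
        assert E.values[0, 0] == pytest.approx(25.1, abs=0.1)
        assert E.units == "t/ha/yr"

    def test_annihilator_and_linearity(self):
        R, K = make_grid([[2000.0]]), make_grid([[0.0]])
        C, S = make_grid([[0.5]]), make_grid([[0.971]])
        assert usle_erosion(R, K, C, S).values[0, 0] == 0.0
        E1 = usle_erosion(make_grid([[1000.0]]), make_grid([[0.02]]), C, S)
        E2 = usle_erosion(make_grid([[2000.0]]), make_grid([[0.02]]), C, S)
        np.testing.assert_allclose(E2.values, 2 * E1.values)

    def test_negative_factor_errors(self):
        with pytest.raises(ValueError):
            usle_erosion(make_grid([[-1.0]]), make_grid([[1.0]]),
                         make_grid([[1.0]]), make_grid([[1.0]]))


def _channel_partition(nr=7, nc=7, cell=100.0, threshold=14):
    r = np.abs(np.arange(nr) - nr // 2)[:, None] * 10.0
    c = np.arange(nc)[None, :]
    dem = make_grid(r - c, cell=cell)
    flow = d8_flow(fill_pits(dem), stream_threshold=threshold)
    return flow, delineate_watersheds(flow)


class TestSedimentLoad:
    def test_uniform_rate_times_area(self):
        flow, ws = _channel_partition()
        E = make_grid(np.ones((7, 7)), cell=100.0)  # 1 t/ha/yr everywhere
        loads = sediment_load(E, ws, cell_area_ha=1.0)
        assert loads.sum() == pytest.approx(ws.records["cells"].sum())

    def test_zero_erosion_zero_load(self):
        flow, ws = _channel_partition()
        E = make_grid(np.zeros((7, 7)), cell=100.0)
        assert sediment_load(E, ws, cell_area_ha=1.0).sum() == 0.0

    def test_additive_over_watersheds(self, scenario64, terrain64):
        rng = np.random.default_rng(2)
        ws = terrain64.watersheds
        E = ws.labels.like(rng.uniform(0, 10, ws.labels.shape))
        loads = sediment_load(E, ws, cell_area_ha=1.0)
        lab = ws.label_array()
        total = E.values[(lab > 0) & E.valid_mask].sum()
        assert loads.sum() == pytest.approx(total)


class TestStreamVelocity:
    def test_two_cell_hand_value(self):
        """Stream cells with slope-area terms {2, 4} and V_m = 1 get
        velocities {2/3, 4/3}, whose mean is V_m."""
        flow, ws = _channel_partition(threshold=36)  # stream: 2 east cells
        assert int(ws.records["stream_cells"].sum()) == 2
        stream = ws.stream_mask
        acc = flow.accumulation
        # pick slope values so s^0.5·A^0.5 = 2 and 4 on the stream cells
        s_vals = np.ones((7, 7))
        (r1, c1), (r2, c2) = np.argwhere(stream)
        s_vals[r1, c1] = 4.0 / acc.values[r1, c1]
        s_vals[r2, c2] = 16.0 / acc.values[r2, c2]
        vm_one = lambda ws_, slope_g, st: pd.Series(1.0, index=ws_.records.index)
        V = stream_velocity(make_grid(s_vals, cell=100.0), acc, ws,
                            vm_strategy=vm_one, fill_offstream=False)
        np.testing.assert_allclose(np.sort(V.values[stream]), [2 / 3, 4 / 3])
        assert V.values[stream].mean() == pytest.approx(1.0)

    def test_uniform_terms_give_vm_everywhere(self):
        flow, ws = _channel_partition(threshold=36)
        stream = ws.stream_mask
        acc_u = flow.accumulation.like(np.ones((7, 7)))
        s_u = make_grid(np.ones((7, 7)), cell=100.0)
        vm = lambda ws_, sg, st: pd.Series(0.42, index=ws_.records.index)
        V = stream_velocity(s_u, acc_u, ws, vm_strategy=vm)
        np.testing.assert_allclose(V.values[stream], 0.42)

    def test_watershed_mean_identity(self, terrain64):
        ws = terrain64.watersheds
        V = stream_velocity(terrain64.slope_deg, terrain64.flow.accumulation,
                            ws)
        lab = ws.label_array()
        stream = ws.stream_mask
        for wid in ws.records.index:
            cells = (lab == wid) & stream
            np.testing.assert_allclose(
                np.nanmean(V.values[cells]),
                ws.records.loc[wid, "velocity_scale_Vm"], atol=1e-9)


class TestSedimentationIndex:
    def test_load_times_complemented_velocity(self):
        load = make_grid([1.0, 0.5, 0.0])
        V = make_grid([0.0, 0.5, 1.0])
        out = sedimentation_index(load, V)
        # raw: [1, 0.25, 0] → renormalized [1, 0.25, 0]
        np.testing.assert_allclose(out.values[0], [1.0, 0.25, 0.0])

    def test_zero_load_zero_index(self):
        load = make_grid([0.0, 0.0, 1.0])
        V = make_grid([0.0, 1.0, 0.5])
        out = sedimentation_index(load, V)
        assert out.values[0, 0] == 0.0 and out.values[0, 1] == 0.0
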