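"""Terrain derivatives: slope, pit filling, D8 routing, TWI,
watershed delineation and the Horton form factor."""

import numpy as np
import pandas as pd
import pytest

from pestfate.terrain import (NEIGHBORS, FlowField, WatershedPartition,
                              d8_flow, delineate_watersheds, fill_pits,
                              horton_form_factor, slope, twi)

from conftest import make_grid


class TestSlope:
    def test_flat_dem_zero(self):
        out = slope(make_grid(np.zeros((5, 5))))
        np.testing.assert_allclose(out.values, 0.0)

    def test_inclined_plane(self):
        # z = 0.1·x on 1 m cells → 10 % ≙ 5.71°
        x = np.arange(6.0)
        dem = make_grid(np.tile(0.1 * x, (5, 1)))
        pct = slope(dem, mode="percent")
        np.testing.assert_allclose(pct.values, 10.0, atol=1e-9)
        deg = slope(dem, mode="degrees")
        np.testing.assert_allclose(deg.values, np.degrees(np.arctan(0.1)))

    def test_nonnegative_on_random_dem(self):
        rng = np.random.default_rng(3)
        out = slope(make_grid(rng.normal(size=(12, 12))))
        assert (out.valid_values() >= 0).all()

    def test_single_row_errors(self):
        with pytest.raises(ValueError):
            slope(make_grid(np.zeros((1, 8))))


def _brute_force_fill(z: np.ndarray) -> np.ndarray:
    """Independent flood oracle: start interior cells at +inf and relax
    f = max(z, min of neighbor f) to a fixed point."""
    f = np.full_like(z, np.inf)
    f[0, :] = z[0, :]; f[-1, :] = z[-1, :]
    f[:, 0] = z[:, 0]; f[:, -1] = z[:, -1]
    changed = True
    while changed:
        changed = False
        for r in range(1, z.shape[0] - 1):
            for c in range(1, z.shape[1] - 1):
                spill = min(f[r + dr, c + dc] for dr, dc in NEIGHBORS)
                want = max(z[r, c], spill)
                if want < f[r, c]:
                    f[r, c] = want
                    changed = True
    return f


class TestFillPits:
    def test_pit_free_unchanged(self):
        x = np.arange(5.0)
        dem = make_grid(np.add.outer(x, x))
        np.testing.assert_array_equal(fill_pits(dem).values, dem.values)

    def test_single_depression_raised_to_spill(self):
        x = np.arange(5.0)
        z = np.add.outer(x, x)
        z[2, 2] = 0.0  # pit on an otherwise draining plane
        out = fill_pits(make_grid(z))
        np.testing.assert_allclose(out.values, _brute_force_fill(z))
        assert out.values[2, 2] == 2.0  # lowest rim neighbor (1,1)

    def test_matches_flood_oracle_on_random_dem(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(5, 5))
        out = fill_pits(make_grid(z))
        np.testing.assert_allclose(out.values, _brute_force_fill(z))

    def test_never_lowers(self):
        rng = np.random.default_rng(11)
        z = rng.normal(size=(16, 16))
        out = fill_pits(make_grid(z))
        assert (out.values - z >= -1e-12).all()


def _oracle_accumulation(flow: FlowField) -> np.ndarray:
    """Brute-force path-following accumulation: every cell contributes 1 to
    each cell on its downstream path (including itself)."""
    dirs = flow.dir_array
    valid = flow.directions.valid_mask
    acc = np.zeros(dirs.shape)
    nr, nc = dirs.shape
    for r0 in range(nr):
        for c0 in range(nc):
            if not valid[r0, c0]:
                continue
            r, c = r0, c0
            for _ in range(dirs.size + 1):
                acc[r, c] += 1
                k = dirs[r, c]
                if k < 0:
                    break
                r, c = r + NEIGHBORS[k][0], c + NEIGHBORS[k][1]
            else:
                raise AssertionError("cycle: path exceeded cell count")
    return acc


class TestD8Flow:
    def test_descending_row(self):
        dem = make_grid([[5.0, 4.0, 3.0, 2.0, 1.0]])
        flow = d8_flow(dem, stream_threshold=3)
        np.testing.assert_array_equal(flow.accumulation.values,
                                      [[1, 2, 3, 4, 5]])

    def test_v_valley_axis_collects_both_slopes(self):
        # valley along the centre column, falling southwards
        col = np.arange(7.0)
        z = np.abs(col - 3)[None, :] * 10 + (6 - np.arange(7.0))[:, None]
        flow = d8_flow(make_grid(z), stream_threshold=100)
        np.testing.assert_array_equal(flow.accumulation.values,
                                      _oracle_accumulation(flow))
        assert flow.accumulation.values[6, 3] == 49  # outlet drains all

    def test_outlet_conservation_and_acyclicity(self, scenario64):
        flow = d8_flow(fill_pits(scenario64["dem"]))
        dirs = flow.dir_array
        outlets = dirs == -1
        assert flow.accumulation.values[outlets].sum() == flow.directions.n_valid()
        assert (flow.accumulation.values[flow.directions.valid_mask] >= 1).all()
        _oracle_accumulation(flow)  # raises on any cycle


class TestTwi:
    def test_direct_evaluation(self):
        s = make_grid([[np.degrees(np.arctan(0.1))]])
        a = make_grid([[1.0]])
        out = twi(s, a, cell_m=1000.0)
        np.testing.assert_allclose(out.values, np.log(10_000.0), rtol=1e-6)

    def test_flat_pixel_finite_via_floor(self):
        out = twi(make_grid([[0.0]]), make_grid([[1.0]]), cell_m=100.0)
        assert np.isfinite(out.values[0, 0])
        np.testing.assert_allclose(out.values[0, 0], np.log(100.0 / 1e-3))

    def test_monotone_in_accumulation(self):
        s = make_grid([[10.0, 10.0]])
        out = twi(s, make_grid([[1.0, 50.0]]), cell_m=100.0)
        assert out.values[0, 1] > out.values[0, 0]


def _channel_dem(nr=7, nc=7, mid=3):
    """Plane draining to a carved channel row that falls eastwards."""
    r = np.abs(np.arange(nr) - mid)[:, None] * 10.0
    c = np.arange(nc)[None, :]
    return make_grid(r - c, cell=100.0)


class TestWatersheds:
    def test_single_stream_single_watershed(self):
        flow = d8_flow(_channel_dem(), stream_threshold=14)
        ws = delineate_watersheds(flow)
        assert len(ws.records) == 1
        assert ws.unassigned_cells == 0
        assert ws.records["cells"].sum() == flow.directions.n_valid()

    def test_stream_length_step_counting(self):
        # channel accumulation: 7·(c+1) ⇒ threshold 21 keeps 5 stream cells
        flow = d8_flow(_channel_dem(), stream_threshold=21)
        ws = delineate_watersheds(flow)
        # 5 stream cells in a straight east-flowing reach, 100 m cells
        assert ws.records["stream_cells"].sum() == 5
        np.testing.assert_allclose(ws.records["stream_length_m"].sum(), 400.0)

    def test_y_confluence_three_segments(self):
        # two diagonal tributary canyons joining a trunk: elevation is
        # 20 × (Chebyshev distance to the channel network) + along-channel
        # position, so every cell drains into the nearest channel arm
        arms = {(r, r): 8 - r for r in range(4)}                   # NW arm
        arms.update({(8 - i, i): 8 - i for i in range(4)})         # SW arm
        arms.update({(4, c): 8 - c for c in range(4, 9)})          # trunk
        z = np.zeros((9, 9))
        for r in range(9):
            for c in range(9):
                d, pp = min((max(abs(r - ar), abs(c - ac)), p)
                            for (ar, ac), p in arms.items())
                z[r, c] = 20 * d + pp
        flow = d8_flow(fill_pits(make_grid(z)), stream_threshold=15)
        ws = delineate_watersheds(flow)
        assert len(ws.records) == 3  # two arms + trunk below the confluence
        total = ws.records["cells"].sum() + ws.unassigned_cells
        assert total == flow.directions.n_valid()

    def test_partition_of_valid_extent(self, terrain64):
        ws = terrain64.watersheds
        total = ws.records["cells"].sum() + ws.unassigned_cells
        assert total == terrain64.flow.directions.n_valid()
        # every stream cell belongs to exactly one watershed
        lab = ws.label_array()
        assert (lab[ws.stream_mask] > 0).all()

    def test_no_streams_errors_with_hint(self):
        flow = d8_flow(_channel_dem(), stream_threshold=10_000)
        with pytest.raises(ValueError, match="threshold"):
            delineate_watersheds(flow)


class TestHortonFormFactor:
    @staticmethod
    def _partition(area_m2=10_000.0, length_m=500.0):
        labels = make_grid([[1.0]])
        rec = pd.DataFrame({"cells": [1], "area_m2": [area_m2],
                            "stream_cells": [1], "stream_length_m": [length_m]},
                           index=pd.Index([1], name="watershed"))
        return WatershedPartition(labels, rec, 0, area_m2,
                                  stream_segments=np.array([[1]]))

    def test_area_over_length(self):
        ff, grid = horton_form_factor(self._partition())
        assert ff.loc[1] == 20.0
        assert grid.values[0, 0] == 20.0

    def test_classical_dialect(self):
        ff, _ = horton_form_factor(self._partition(),
                                   dialect="area_over_length2")
        np.testing.assert_allclose(ff.loc[1], 0.04)

    def test_unknown_dialect_errors(self):
        with pytest.raises(ValueError):
            horton_form_factor(self._partition(), dialect="length_over_area")
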