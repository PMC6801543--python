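"""Leaching, runoff, storage/filtering and volatilization overlays:
worked values, orientation, monotonicity and the binary-indicator
equivalence of the runoff score."""

import itertools

import numpy as np
import pytest

from pestfate.grid import GridStack, combine_linear, complement
from pestfate.leaching import (LeachingInputs, drainage_class_score,
                               leaching_vulnerability)
from pestfate.runoff import (RunoffInputs, landuse_weights,
                             runoff_accumulation, runoff_generation,
                             runoff_transfer, topography_indicator)
from pestfate.storage_filtering import SfcInputs, sfc
from pestfate.volatilization import (VolatInputs, annual_summary,
                                     monthly_volatilization, normalize_stack)

from conftest import make_grid


def _leach_inputs(d, gw, db, sl, sm):
    return LeachingInputs(*(make_grid([[float(v)]]) for v in (d, gw, db, sl, sm)))


class TestLeaching:
    def test_drainage_class_scores(self):
        g = make_grid([1.0, 2.0, 3.0])
        out = drainage_class_score(g)
        np.testing.assert_allclose(out.values[0], [0.0, 0.5, 1.0])

    def test_unknown_drainage_class_errors(self):
        with pytest.raises(ValueError, match="unknown drainage class"):
            drainage_class_score(make_grid([4.0]))

    @pytest.mark.parametrize("inputs,expected", [
        ((1, 0, 0, 0, 1), 18.0),   # every term maximal: 5+5+2+1+5
        ((0, 1, 1, 1, 0), 0.0),    # every term vanishes
        ((0.5,) * 5, 9.0),         # half of the span, by linearity
    ])
    def test_raw_score_worked_values(self, inputs, expected):
        out = leaching_vulnerability(_leach_inputs(*inputs), normalize=False)
        np.testing.assert_allclose(out.values[0, 0], expected)

    def test_input_outside_unit_interval_errors(self):
        with pytest.raises(ValueError):
            _leach_inputs(1.2, 0, 0, 0, 0)

    def test_monotone_orientation(self):
        rng = np.random.default_rng(8)
        base = [make_grid(rng.uniform(0, 1, (6, 6))) for _ in range(5)]
        raw = leaching_vulnerability(LeachingInputs(*base), normalize=False)
        for idx, direction in [(0, +1), (1, -1), (2, -1), (3, -1), (4, +1)]:
            bumped = list(base)
            bumped[idx] = bumped[idx].like(
                np.clip(bumped[idx].values + 0.1, 0, 1))
            raw2 = leaching_vulnerability(LeachingInputs(*bumped),
                                          normalize=False)
            diff = direction * (raw2.values - raw.values)
            assert (diff >= -1e-12).all()

    def test_linearity_in_inputs(self):
        rng = np.random.default_rng(9)
        a = [make_grid(rng.uniform(0, 1, (4, 4))) for _ in range(5)]
        b = [make_grid(rng.uniform(0, 1, (4, 4))) for _ in range(5)]
        alpha = 0.3
        mix = [g.like(alpha * ga.values + (1 - alpha) * gb.values)
               for g, ga, gb in zip(a, a, b)]
        La = leaching_vulnerability(LeachingInputs(*a), normalize=False).values
        Lb = leaching_vulnerability(LeachingInputs(*b), normalize=False).values
        Lm = leaching_vulnerability(LeachingInputs(*mix), normalize=False).values
        np.testing.assert_allclose(Lm, alpha * La + (1 - alpha) * Lb,
                                   atol=1e-10)


def _runoff_inputs(**kw):
    defaults = dict(drainage_score=0.0, soil_thickness=0.0, erodibility_K=0.0,
                    slope_n=0.0, twi_n=0.0, landuse_w=0.0, form_factor_n=0.0,
                    flow_acc_n=0.0)
    defaults.update(kw)
    return RunoffInputs(**{k: make_grid([[float(v)]])
                           for k, v in defaults.items()})


class TestRunoff:
    @pytest.mark.parametrize("cls,weight", [
        (1, 0.0),    # forest
        (4, 0.8),    # irrigated and rain-fed cultivated land
        (5, 1.0),    # built-up land
        (2, 0.2), (3, 0.6),
    ])
    def test_landuse_weight_table(self, cls, weight):
        out = landuse_weights(make_grid([[float(cls)]]))
        assert out.values[0, 0] == weight

    def test_unmapped_class_errors_naming_it(self):
        with pytest.raises(ValueError, match="9"):
            landuse_weights(make_grid([[9.0]]))

    def test_topography_indicator_is_mean(self):
        out = topography_indicator(make_grid([[0.2]]), make_grid([[0.6]]))
        np.testing.assert_allclose(out.values[0, 0], 0.4)

    def test_generation_raw_mean_of_five(self):
        # oriented indicators (1,0,0,0,0): impermeable soil only
        x = _runoff_inputs(drainage_score=0.0, soil_thickness=1.0)
        out = runoff_generation(x, normalize=False)
        np.testing.assert_allclose(out.values[0, 0], 0.2)

    def test_transfer_raw_mean(self):
        gen = runoff_generation(_runoff_inputs(), normalize=False)
        gen = gen.like(np.full((1, 1), 0.9))
        from pestfate.grid import as_process_map
        out = runoff_transfer(as_process_map(gen, "g"), make_grid([[0.6]]),
                              make_grid([[0.3]]), normalize=False)
        np.testing.assert_allclose(out.values[0, 0], 0.6)

    def test_accumulation_endpoints_and_mean(self):
        from pestfate.grid import as_process_map
        gen = as_process_map(make_grid([[1.0]]), "g")
        out = runoff_accumulation(gen, make_grid([[0.0]]), make_grid([[1.0]]),
                                  make_grid([[1.0]]), normalize=False)
        np.testing.assert_allclose(out.values[0, 0], 1.0)
        gen5 = as_process_map(make_grid([[0.5]]), "g")
        out5 = runoff_accumulation(gen5, make_grid([[0.5]]), make_grid([[0.5]]),
                                   make_grid([[0.5]]), normalize=False)
        np.testing.assert_allclose(out5.values[0, 0], 0.5)

    def test_binary_indicator_equivalence_with_integer_score(self):
        """On all 2^5 binary indicator combinations the continuous
        generation score × 5 equals the classical integer indicator sum."""
        for bits in itertools.product([0, 1], repeat=5):
            perm, thin, erod, topo, lu = bits
            x = _runoff_inputs(drainage_score=1 - perm, soil_thickness=1 - thin,
                               erodibility_K=erod, slope_n=topo, twi_n=topo,
                               landuse_w=lu)
            out = runoff_generation(x, normalize=False)
            assert out.values[0, 0] * 5 == pytest.approx(sum(bits), abs=1e-12)


def _sfc_inputs(oc, clay, ph, cec):
    return SfcInputs(*(make_grid([[float(v)]]) for v in (oc, clay, ph, cec)))


class TestStorageFiltering:
    @pytest.mark.parametrize("inputs,expected", [
        ((1, 1, 0, 1), 4.0),
        ((0, 0, 1, 0), 0.0),
        ((0.5, 0.5, 0.5, 0.5), 2.0),
    ])
    def test_raw_sum_worked_values(self, inputs, expected):
        out = sfc(_sfc_inputs(*inputs), normalize=False)
        np.testing.assert_allclose(out.values[0, 0], expected)

    def test_equals_combine_linear_oracle(self):
        rng = np.random.default_rng(12)
        grids = [make_grid(rng.uniform(0, 1, (8, 8))) for _ in range(4)]
        out = sfc(SfcInputs(*grids), normalize=False)
        oracle = combine_linear([(1.0, grids[0]), (1.0, grids[1]),
                                 (1.0, complement(grids[2])), (1.0, grids[3])])
        np.testing.assert_allclose(out.values, oracle.values, atol=1e-12)

    def test_ph_decreases_sfc(self):
        lo = sfc(_sfc_inputs(0.5, 0.5, 0.2, 0.5), normalize=False)
        hi = sfc(_sfc_inputs(0.5, 0.5, 0.9, 0.5), normalize=False)
        assert hi.values[0, 0] < lo.values[0, 0]


def _stack(val_by_month):
    return GridStack({m: make_grid([[float(val_by_month(m))]])
                      for m in range(1, 13)}, temporal=True)


class TestVolatilization:
    def _inputs(self, wv=0.5, srad=0.5, t=0.5, rh=0.5, pet=0.5):
        return VolatInputs(_stack(lambda m: wv), _stack(lambda m: srad),
                           _stack(lambda m: t), _stack(lambda m: rh),
                           make_grid([[float(pet)]]))

    @pytest.mark.parametrize("kw,expected", [
        (dict(wv=1, srad=1, t=1, pet=1, rh=0), 5.0),
        (dict(wv=0, srad=0, t=0, pet=0, rh=1), 0.0),
        (dict(), 2.5),
    ])
    def test_monthly_score(self, kw, expected):
        out = monthly_volatilization(self._inputs(**kw), 6)
        np.testing.assert_allclose(out.values[0, 0], expected)

    def test_month_out_of_range_errors(self):
        with pytest.raises(ValueError):
            monthly_volatilization(self._inputs(), 13)

    def test_constant_year_has_zero_sd(self):
        months = _stack(lambda m: 0.7)
        mean_map, sd = annual_summary(months)
        np.testing.assert_allclose(sd.values, 0.0, atol=1e-12)

    def test_alternating_months_mean_and_sd(self):
        months = _stack(lambda m: m % 2)  # six 0s, six 1s
        stack = np.array([months[m].values[0, 0] for m in range(1, 13)])
        _, sd = annual_summary(months)
        assert stack.mean() == 0.5
        np.testing.assert_allclose(sd.values[0, 0], 0.5)

    def test_mean_equals_combine_over_months(self):
        rng = np.random.default_rng(4)
        months = GridStack({m: make_grid(rng.uniform(0, 5, (5, 5)))
                            for m in range(1, 13)}, temporal=True)
        _, _ = annual_summary(months)
        oracle = combine_linear([(1 / 12, months[m]) for m in range(1, 13)])
        stack = np.stack([months[m].values for m in range(1, 13)])
        np.testing.assert_allclose(stack.mean(axis=0), oracle.values,
                                   atol=1e-12)

    def test_stack_normalization_spans_unit_interval_jointly(self):
        months = _stack(lambda m: float(m))  # 1..12
        out = normalize_stack(months)
        vals = [out[m].values[0, 0] for m in range(1, 13)]
        assert vals[0] == 0.0 and vals[-1] == 1.0
        assert all(b > a for a, b in zip(vals, vals[1:]))
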