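"""Growth curve, calibration, cycle-length draws and lineage simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sacsize.growth import (
    CycleTimeModel,
    GrowthParams,
    compute_growth_rate,
    divide,
    draw_cycle_length,
    growth_curve,
    simulate_entry_sizes,
    simulate_lineage,
    simulate_withdrawal,
    time_at_size,
)


class TestCalibration:
    @pytest.mark.parametrize(
        "A0, Amax, T, expected",
        [
            (20, 120, 100, math.log(2.5) / 100),  # = 0.009163, printed ~0.0092
            (10, 100, 50, math.log(180 / 80) / 50),
            (20, 1e9, 100, math.log(2) / 100),  # exponential limit
        ],
    )
    def test_closed_form(self, A0, Amax, T, expected):
        assert compute_growth_rate(A0, Amax, T) == pytest.approx(expected, rel=1e-4)

    def test_rejects_unattainable_doubling(self):
        with pytest.raises(ValueError):
            compute_growth_rate(60, 120, 100)

    def test_doubling_identity(self, params_m0):
        # with r from the calibration and m=0, A(T) = 2*A0 exactly
        assert growth_curve(params_m0, params_m0.T_unperturbed) == pytest.approx(
            2 * params_m0.A0, rel=1e-12
        )


class TestGrowthCurve:
    def test_starts_at_A0(self, params):
        assert growth_curve(params, 0.0) == pytest.approx(params.A0)

    def test_linear_term_scales_doubled_size(self):
        p = GrowthParams(m=0.05)
        expected = 40.0 * (1 + 0.05 * 100 / 120)
        assert growth_curve(p, 100.0) == pytest.approx(expected, rel=1e-9)

    def test_saturates_at_Amax_when_m_zero(self, params_m0):
        assert growth_curve(params_m0, 5000.0) == pytest.approx(params_m0.Amax, rel=1e-6)

    def test_approaches_slope_m_for_large_t(self, params):
        t = np.array([5000.0, 5100.0])
        a = growth_curve(params, t)
        assert (a[1] - a[0]) / 100.0 == pytest.approx(params.m, rel=1e-3)

    @given(st.floats(0.0, 2000.0), st.floats(0.1, 500.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_strictly_increasing(self, t, gap):
        p = GrowthParams()
        assert growth_curve(p, t + gap) > growth_curve(p, t)

    def test_rejects_negative_time(self, params):
        with pytest.raises(ValueError):
            growth_curve(params, -1.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GrowthParams(A0=-1)
        with pytest.raises(ValueError):
            GrowthParams(A0=70, Amax=120)
        with pytest.raises(ValueError):
            GrowthParams(m=-0.1)


class TestTimeAtSize:
    def test_at_origin(self, params):
        assert time_at_size(params, params.A0) == 0.0

    def test_doubling_point(self, params_m0):
        assert time_at_size(params_m0, 40.0) == pytest.approx(100.0, abs=1e-6)

    def test_roundtrip(self, params, rng):
        for t in rng.uniform(0.0, 1000.0, 100):
            a = growth_curve(params, t)
            assert time_at_size(params, a) == pytest.approx(t, abs=1e-6)

    def test_out_of_range(self, params_m0, params):
        with pytest.raises(ValueError):
            time_at_size(params_m0, 10.0)
        with pytest.raises(ValueError):
            time_at_size(params_m0, 120.0)
        # unbounded for m > 0
        assert time_at_size(params, 500.0) > 0


class TestCycleDraws:
    def test_unperturbed_moments(self, unperturbed, rng):
        d = draw_cycle_length(unperturbed, rng, size=100_000)
        assert d.mean() == pytest.approx(100.0, abs=0.5)
        assert d.std() == pytest.approx(10.0, abs=0.5)
        assert np.all(d > 0)

    def test_sac_moments(self, sac, rng):
        d = draw_cycle_length(sac, rng, size=100_000)
        assert d.mean() == pytest.approx(400.0, abs=3.0)
        # delay adds to the mean only: CV -> 200/400 = 0.5
        assert d.std() / d.mean() == pytest.approx(0.5, abs=0.01)
        assert d.min() >= 200.0

    def test_reproducible_under_seed(self, sac):
        a = draw_cycle_length(sac, np.random.default_rng(5), size=100)
        b = draw_cycle_length(sac, np.random.default_rng(5), size=100)
        np.testing.assert_array_equal(a, b)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            CycleTimeModel(regime="unperturbed", mean=100, sd=0)
        with pytest.raises(ValueError):
            CycleTimeModel(regime="sac_active", mean=200, delay=0)
        with pytest.raises(ValueError):
            CycleTimeModel(regime="weird", mean=1)


class TestDivide:
    def test_halves_to_origin(self, params):
        post, t0 = divide(params, 2 * params.A0)
        assert post == params.A0 and t0 == 0.0

    def test_doubling_construction(self, params_m0):
        post, t = divide(params_m0, 80.0)
        assert post == 40.0
        assert t == pytest.approx(100.0, abs=1e-6)

    def test_divide_then_grow_restores_predivision_size(self, params_m0):
        # doubling in T holds at the calibration point: a cell dividing
        # at 2*A0 returns to 2*A0 after one unperturbed cycle
        post, t = divide(params_m0, 2 * params_m0.A0)
        regrown = growth_curve(params_m0, t + params_m0.T_unperturbed)
        assert regrown == pytest.approx(2 * params_m0.A0, rel=1e-9)

    def test_below_origin_clamps_with_warning(self, params):
        with pytest.warns(RuntimeWarning):
            post, t = divide(params, 1.5 * params.A0)
        assert post == params.A0 and t == 0.0


class TestLineage:
    def test_single_deterministic_cycle_doubles(self):
        p = GrowthParams(m=0.0)
        near_fixed = CycleTimeModel.unperturbed(mean=100.0, sd=1e-9)
        trace = simulate_lineage(
            p, [(0.0, near_fixed)], n_cycles=1, dt=10.0, rng=np.random.default_rng(0)
        )
        assert len(trace.divisions) == 1
        assert trace.divisions.pre_area_um2.iloc[0] == pytest.approx(2 * p.A0, rel=1e-6)
        assert trace.divisions.post_area_um2.iloc[0] == pytest.approx(p.A0, rel=1e-6)

    def test_unperturbed_division_sizes_near_periodic(self, params_m0, unperturbed):
        trace = simulate_lineage(
            params_m0,
            [(0.0, unperturbed)],
            n_cycles=50,
            rng=np.random.default_rng(2),
        )
        pre = trace.divisions.pre_area_um2.to_numpy()
        assert pre.std(ddof=1) / pre.mean() < 0.15

    def test_sac_cycle_time_cv_exceeds_size_cv(self, params, unperturbed, sac):
        # after switching to the SAC regime, cycling times vary more than sizes
        trace = simulate_lineage(
            params,
            [(-1e9, unperturbed), (0.0, sac)],
            n_cycles=25,
            rng=np.random.default_rng(3),
        )
        div = trace.divisions.iloc[3:20]
        lengths = np.diff(trace.divisions.time_min.to_numpy())[2:19]
        sizes = div.post_area_um2.to_numpy()
        cv = lambda v: v.std(ddof=1) / v.mean()
        assert cv(lengths) > cv(sizes)

    def test_fixed_seed_bitwise_identical(self, params, unperturbed):
        mk = lambda: simulate_lineage(
            params, [(0.0, unperturbed)], n_cycles=10, rng=np.random.default_rng(9)
        )
        a, b = mk(), mk()
        assert a.samples.equals(b.samples)
        assert a.divisions.equals(b.divisions)

    def test_division_halves_size(self, params, sac):
        trace = simulate_lineage(
            params, [(0.0, sac)], n_cycles=5, rng=np.random.default_rng(4)
        )
        np.testing.assert_allclose(
            trace.divisions.post_area_um2, trace.divisions.pre_area_um2 / 2
        )

    def test_schedule_validation(self, params, unperturbed, sac):
        with pytest.raises(ValueError):
            simulate_lineage(
                params, [(0.0, unperturbed), (-5.0, sac)], 2, rng=np.random.default_rng(0)
            )
        with pytest.raises(ValueError):
            simulate_lineage(params, [(10.0, unperturbed)], 2, rng=np.random.default_rng(0))


class TestEntrySizeDynamics:
    def test_combined_curve_stabilizes_log_variance(self, params, sac):
        e = simulate_entry_sizes(params, sac, 500, 30, np.random.default_rng(7))
        v10 = np.var(np.log(e[:, 9]))
        v30 = np.var(np.log(e[:, 29]))
        assert v30 <= 1.5 * v10

    def test_pure_exponential_log_variance_grows_linearly(self, params, sac):
        e = simulate_entry_sizes(
            params, sac, 500, 30, np.random.default_rng(7), growth="exponential"
        )
        log_var = np.array([np.var(np.log(e[:, k])) for k in range(30)])
        # unbounded growth: variance keeps increasing, ~linearly in cycle count
        slope = np.polyfit(np.arange(30), log_var, 1)[0]
        per_cycle = (params.r * 200.0) ** 2  # r^2 * Var(T)
        assert slope == pytest.approx(per_cycle, rel=0.25)
        assert log_var[-1] > 5 * log_var[4]


class TestWithdrawal:
    def test_entry_medians_converge_monotonically(self, params):
        wd = simulate_withdrawal(params, 200, 12, 5, np.random.default_rng(3))
        med = wd.groupby("cycle")["entry_area_um2"].median()
        assert list(med.index) == [0, 1, 2, 3, 4, 5]
        assert np.all(np.diff(med.to_numpy()) < 0)
        unp_steady = simulate_entry_sizes(
            params, CycleTimeModel.unperturbed(), 300, 15, np.random.default_rng(4)
        )[:, -1]
        assert med.iloc[-1] > np.median(unp_steady)  # approaches from above

    def test_zero_cycles_after_returns_sac_steady_only(self, params):
        wd = simulate_withdrawal(params, 50, 8, 0, np.random.default_rng(1))
        assert set(wd.cycle) == {0}
        assert len(wd) == 50
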