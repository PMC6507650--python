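"""Outlier filtering, smoothing, derivatives, binning and averaging of
size trajectories."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sacsize.trajectories import (
    ClusterThresholds,
    SizeTrajectory,
    adjust_trajectory,
    bin_means,
    fit_thresholds,
    local_growth_rate,
    local_variations,
    mean_trajectory,
    pixels_to_area,
    smooth,
    smoothing_window,
)


def traj(areas, dt=10.0, **kw):
    areas = np.asarray(areas, dtype=float)
    return SizeTrajectory(times=np.arange(areas.size) * dt, areas=areas, **kw)


WIDE = ClusterThresholds(bounds=((-100, 100),) * 3)
TIGHT = ClusterThresholds(bounds=((-3, 3),) * 3)


class TestLocalVariations:
    def test_simple_differences(self):
        np.testing.assert_array_equal(local_variations(traj([20, 22, 25])), [2, 3])

    def test_constant_is_zero(self):
        assert np.all(local_variations(traj([30] * 5)) == 0)

    @given(
        arrays(np.float64, st.integers(2, 30), elements=st.floats(1.0, 200.0))
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_telescoping_sum(self, areas):
        d = local_variations(traj(areas))
        assert d.sum() == pytest.approx(areas[-1] - areas[0], abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            local_variations(traj([20.0]))


class TestPixelsToArea:
    @pytest.mark.parametrize("px, um2", [(0, 0.0), (400, 20.0), (2400, 120.0)])
    def test_conversion(self, px, um2):
        assert pixels_to_area(px) == pytest.approx(um2)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pixels_to_area(-1)


class TestFitThresholds:
    def test_degenerate_iqr_flags_single_jump(self):
        # 100 points, all variations 0 except one of +10: IQR is 0, the
        # fences collapse onto 0 and the jump violates them
        areas = np.full(101, 30.0)
        areas[60:] += 10.0
        thr = fit_thresholds([traj(areas)])
        lo, hi = thr.bounds[0]
        assert lo == 0.0 and hi == 0.0
        assert thr.violates(30.0, 10.0)
        assert not thr.violates(30.0, 0.0)

    def test_quartile_convention_linear_interpolation(self):
        diffs = np.arange(1.0, 9.0)
        areas = np.concatenate([[1.0], 1.0 + np.cumsum(diffs)])  # all <= 40
        thr = fit_thresholds([traj(areas)])
        q1, q3 = np.quantile(diffs, [0.25, 0.75])  # type-7 oracle
        iqr = q3 - q1
        assert thr.bounds[0] == pytest.approx((q1 - 1.5 * iqr, q3 + 1.5 * iqr))

    def test_symmetric_distribution_gives_symmetric_bounds(self):
        diffs = np.array([-4, -2, -1, 1, 2, 4, -3, 3], dtype=float)
        areas = np.concatenate([[20.0], 20.0 + np.cumsum(diffs)])
        thr = fit_thresholds([traj(areas)])
        lo, hi = thr.bounds[0]
        assert lo == pytest.approx(-hi)

    def test_empty_cluster_left_unset_and_never_flagged(self):
        thr = fit_thresholds([traj([20, 21, 22, 23, 24])])
        assert thr.bounds[1] is None and thr.bounds[2] is None
        assert not thr.violates(60.0, 1e6)

    def test_above_top_edge_never_flagged(self):
        assert not WIDE.violates(150.0, 1e6)


class TestAdjustTrajectory:
    def test_clean_trajectory_is_fixed_point(self):
        t = traj([20, 21, 22, 23])
        adj, sweeps = adjust_trajectory(t, WIDE)
        np.testing.assert_array_equal(adj.areas, t.areas)
        assert sweeps == 0 and not adj.adjusted_flags.any()

    def test_single_spike_replaced_by_neighbour_mean(self):
        adj, sweeps = adjust_trajectory(traj([20, 21, 50, 23, 24]), TIGHT)
        np.testing.assert_allclose(adj.areas, [20, 21, 22, 23, 24])
        assert sweeps == 1
        np.testing.assert_array_equal(
            adj.adjusted_flags, [False, False, True, False, False]
        )

    def test_adjacent_spikes_resolved_within_ten_iterations(self):
        adj, sweeps = adjust_trajectory(traj([20, 21, 50, 55, 24, 25]), TIGHT)
        assert sweeps <= 10
        assert adj.adjusted_flags[2] and adj.adjusted_flags[3]
        # both spikes pulled back to the neighbourhood of the clean level
        assert np.all(adj.areas[2:4] < 30)
        # converged: one more pass changes nothing
        again, more = adjust_trajectory(adj, TIGHT)
        np.testing.assert_array_equal(again.areas, adj.areas)
        assert more == 0

    def test_endpoints_never_replaced(self):
        adj, _ = adjust_trajectory(traj([90, 21, 22, 23, 90]), TIGHT)
        assert adj.areas[0] == 90 and adj.areas[-1] == 90
        assert not adj.adjusted_flags[0] and not adj.adjusted_flags[-1]

    def test_preserves_length_and_unflagged_points(self):
        t = traj([20, 21, 50, 23, 24])
        adj, _ = adjust_trajectory(t, TIGHT)
        assert len(adj) == len(t)
        untouched = ~adj.adjusted_flags
        np.testing.assert_array_equal(adj.areas[untouched], t.areas[untouched])


class TestSmooth:
    def test_window_one_is_identity(self):
        t = traj([5, 1, 9, 2])
        np.testing.assert_array_equal(smooth(t, 1).areas, t.areas)

    def test_constant_unchanged(self):
        t = traj([7.0] * 10)
        np.testing.assert_allclose(smooth(t, 5).areas, 7.0)

    def test_interior_moving_average(self):
        sm = smooth(traj([1, 2, 3, 4, 5]), 3)
        np.testing.assert_allclose(sm.areas[1:-1], [2, 3, 4])

    def test_commutes_with_additive_constant(self, rng):
        a = rng.uniform(10, 50, 20)
        base = smooth(traj(a), 3).areas
        shifted = smooth(traj(a + 11.5), 3).areas
        np.testing.assert_allclose(shifted, base + 11.5, rtol=1e-12)

    def test_reduces_white_noise_variance(self, rng):
        a = 50 + rng.normal(0, 2, 200)
        assert smooth(traj(a), 5).areas.var() < a.var()

    def test_condition_defaults(self):
        assert smoothing_window("unperturbed") == 3
        assert smoothing_window("gen0-sac") == 8

    def test_window_larger_than_series_rejected(self):
        with pytest.raises(ValueError):
            smooth(traj([1, 2, 3]), 4)


class TestLocalGrowthRate:
    def test_linear_trajectory_recovers_slope(self):
        t = np.arange(10) * 10.0
        tr = SizeTrajectory(times=t, areas=5.0 + 0.4 * t)
        np.testing.assert_allclose(local_growth_rate(tr), 0.4, rtol=1e-12)

    def test_constant_trajectory_is_zero(self):
        assert np.all(local_growth_rate(traj([9.0] * 6)) == 0)

    def test_exponential_closed_form(self):
        r, dt = 0.01, 10.0
        t = np.arange(20) * dt
        tr = SizeTrajectory(times=t, areas=np.exp(r * t))
        expected = np.exp(r * t[1:-1]) * np.sinh(r * dt) / dt
        np.testing.assert_allclose(local_growth_rate(tr)[1:-1], expected, rtol=1e-12)

    def test_nonuniform_spacing_warns_but_uses_actual_gaps(self):
        tr = SizeTrajectory(times=np.array([0.0, 10.0, 30.0]), areas=np.array([1.0, 2.0, 4.0]))
        with pytest.warns(UserWarning):
            d = local_growth_rate(tr)
        assert d[1] == pytest.approx((4 - 1) / 30)


class TestBinMeans:
    def test_two_bins(self):
        out = bin_means([5, 15], [1, 3], 10)
        np.testing.assert_allclose(out.x_mean, [5, 15])
        np.testing.assert_allclose(out.y_mean, [1, 3])
        np.testing.assert_array_equal(out.n, [1, 1])

    def test_single_bin_overall_mean(self):
        out = bin_means([1, 2, 3], [4, 5, 9], 10)
        assert len(out) == 1
        assert out.y_mean.iloc[0] == pytest.approx(6.0)

    def test_matches_brute_force_oracle(self, rng):
        x = rng.uniform(0, 100, 500)
        y = rng.normal(size=500)
        w = 10.0
        out = bin_means(x, y, w)
        for _, row in out.iterrows():
            mask = (x >= row.bin * w) & (x < (row.bin + 1) * w)
            assert row.n == mask.sum()
            assert row.x_mean == pytest.approx(x[mask].mean())
            assert row.y_mean == pytest.approx(y[mask].mean())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bin_means([], [], 10)


class TestMeanTrajectory:
    def test_identical_trajectories(self):
        trajs = [traj([20, 25, 30]) for _ in range(6)]
        out = mean_trajectory(trajs)
        np.testing.assert_allclose(out.mean_area_um2, [20, 25, 30])

    def test_five_trajectories_insufficient(self):
        out = mean_trajectory([traj([20, 25, 30]) for _ in range(5)])
        assert out.empty  # strictly more than five required

    def test_support_cutoff_matches_count_oracle(self):
        # 8 trajectories of length 5, 3 of length 10: only the first five
        # timepoints have more than 5 contributors
        trajs = [traj(np.linspace(20, 30, 5)) for _ in range(8)]
        trajs += [traj(np.linspace(20, 40, 10)) for _ in range(3)]
        out = mean_trajectory(trajs)
        assert len(out) == 5
        assert np.all(out.n == 11)

    def test_alignment_on_own_start(self):
        late = SizeTrajectory(times=np.array([500.0, 510, 520]), areas=np.array([20.0, 25, 30]))
        trajs = [traj([20, 25, 30]) for _ in range(5)] + [late]
        out = mean_trajectory(trajs)
        assert len(out) == 3  # the late starter aligns onto the shared grid
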