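"""MSD estimation, directed-plus-diffusive model fit and diffusive fraction."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tumotrack.scenario import ValidationError
from tumotrack.tracking import Trajectory
from tumotrack.motility import (
    MotilityFit,
    MSDCurve,
    compare_fd,
    compute_msd,
    diffusive_fraction,
    fit_msd,
    fit_trajectory,
    population_msd,
    summarize_population,
)


def traj_1d(xs, dt=1.0):
    xs = np.asarray(xs, dtype=float)
    pos = np.column_stack([xs, np.zeros_like(xs), np.zeros_like(xs)])
    return Trajectory(0, np.arange(len(xs)) * dt, pos)


def brute_force_msd(traj, max_lag_frames):
    """Independent oracle: explicit double loop over all ordered pairs."""
    out = []
    pos = traj.positions
    for lag in range(1, max_lag_frames + 1):
        acc = []
        for i in range(len(pos) - lag):
            acc.append(np.sum((pos[i + lag] - pos[i]) ** 2))
        out.append(np.mean(acc))
    return np.asarray(out)


class TestComputeMSD:
    def test_hand_computed_short_trajectory(self):
        curve = compute_msd(traj_1d([0.0, 1.0, 3.0]), max_lag_h=1.0)
        assert curve.msd[0] == pytest.approx((1.0 + 4.0) / 2.0)
        # lag 2 uses the single pair (0 -> 3)
        full = brute_force_msd(traj_1d([0.0, 1.0, 3.0]), 2)
        assert full[1] == pytest.approx(9.0)

    def test_ballistic_closed_form(self):
        xs = 3.0 * np.arange(20)
        curve = compute_msd(traj_1d(xs), max_lag_h=10.0)
        np.testing.assert_allclose(curve.msd, 9.0 * curve.lags_h ** 2, rtol=1e-12)

    def test_stationary_zero(self):
        curve = compute_msd(traj_1d(np.zeros(10)), max_lag_h=5.0)
        np.testing.assert_array_equal(curve.msd, 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(5, 31)
            pos = rng.normal(0, 5, size=(n, 3))
            traj = Trajectory(0, np.arange(n, dtype=float), pos)
            max_lag = int(n - 1)
            curve = compute_msd(traj, max_lag_h=max_lag - 0.5)
            oracle = brute_force_msd(traj, max_lag - 1)
            np.testing.assert_allclose(curve.msd, oracle, rtol=1e-10)

    def test_lag_must_be_below_duration(self):
        with pytest.raises(ValidationError):
            compute_msd(traj_1d(np.zeros(5)), max_lag_h=10.0)


class TestFitMSD:
    def test_exact_polynomial_recovery(self):
        tau = np.arange(1.0, 6.0)
        curve = MSDCurve(tau, 8.0 * tau + tau ** 2, np.full(5, 10))
        fit = fit_msd(curve)
        assert fit.D == pytest.approx(2.0, abs=1e-10)
        assert fit.v == pytest.approx(1.0, abs=1e-10)

    def test_ballistic_curve(self):
        tau = np.arange(1.0, 8.0)
        fit = fit_msd(MSDCurve(tau, 9.0 * tau ** 2, np.full(7, 5)))
        assert fit.v == pytest.approx(3.0, abs=1e-10)
        assert fit.D == pytest.approx(0.0, abs=1e-10)

    def test_nonnegativity_clipping(self):
        # strongly concave curve would want b < 0; clipped solution keeps v = 0
        tau = np.arange(1.0, 8.0)
        fit = fit_msd(MSDCurve(tau, 20.0 * np.sqrt(tau), np.full(7, 5)))
        assert fit.D >= 0.0
        assert fit.v >= 0.0

    def test_needs_three_lags(self):
        with pytest.raises(ValidationError):
            fit_msd(MSDCurve(np.array([1.0, 2.0]), np.array([1.0, 2.0]),
                             np.array([1, 1])))

    def test_scale_covariance(self):
        """Positions scaled by s give D·s² and v·s."""
        rng = np.random.default_rng(1)
        pos = np.cumsum(rng.normal(0, 1, size=(40, 3)), axis=0) \
            + 0.5 * np.arange(40)[:, None]
        s = 3.0
        t = np.arange(40, dtype=float)
        fit1 = fit_msd(compute_msd(Trajectory(0, t, pos), 10.0))
        fit2 = fit_msd(compute_msd(Trajectory(0, t, s * pos), 10.0))
        assert fit2.D == pytest.approx(s ** 2 * fit1.D, rel=1e-8)
        assert fit2.v == pytest.approx(s * fit1.v, rel=1e-8)


class TestDiffusiveFraction:
    def test_pure_diffusion_limit(self):
        fit = MotilityFit(D=5.0, v=0.0, f_D=np.nan, residual=0.0, n_lags=5)
        assert diffusive_fraction(fit) == 1.0

    def test_pure_directed_limit(self):
        fit = MotilityFit(D=0.0, v=2.0, f_D=np.nan, residual=0.0, n_lags=5)
        assert diffusive_fraction(fit) == 0.0

    def test_closed_form_value(self):
        fit = MotilityFit(D=2.0, v=1.0, f_D=np.nan, residual=0.0, n_lags=5)
        assert diffusive_fraction(fit, t_d=10.0) == pytest.approx(1.0 / (1.0 + 10.0 / 8.0),
                                                                  abs=1e-9)

    def test_stationary_undefined(self):
        fit = MotilityFit(D=0.0, v=0.0, f_D=np.nan, residual=0.0, n_lags=5)
        assert np.isnan(diffusive_fraction(fit))
        assert fit.undefined

    def test_invalid_lag(self):
        fit = MotilityFit(D=1.0, v=1.0, f_D=np.nan, residual=0.0, n_lags=5)
        with pytest.raises(ValidationError):
            diffusive_fraction(fit, t_d=0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(d=st.floats(0.01, 100.0), v=st.floats(0.01, 50.0),
           t_d=st.floats(0.1, 100.0))
    def test_bounds_and_monotonicity(self, d, v, t_d):
        """f_D ∈ (0,1); decreasing in v and t_D, increasing in D."""
        def fd(dd, vv, tt):
            fit = MotilityFit(D=dd, v=vv, f_D=np.nan, residual=0.0, n_lags=3)
            return diffusive_fraction(fit, t_d=tt)
        base = fd(d, v, t_d)
        assert 0.0 < base < 1.0
        assert fd(d * 1.5, v, t_d) > base
        assert fd(d, v * 1.5, t_d) < base
        assert fd(d, v, t_d * 1.5) < base


class TestPopulationAnalyses:
    def test_identical_trajectories_zero_sd(self):
        xs = np.arange(15, dtype=float)
        trajs = [traj_1d(xs), traj_1d(xs)]
        table = population_msd(trajs, max_lag_h=5.0)
        np.testing.assert_allclose(table["msd_sd"], 0.0)
        np.testing.assert_allclose(table["msd_mean"], table["lag_h"] ** 2)

    def test_two_ballistic_cells_mean(self):
        t = np.arange(12, dtype=float)
        trajs = [traj_1d(1.0 * t), traj_1d(3.0 * t)]
        table = population_msd(trajs, max_lag_h=5.0)
        np.testing.assert_allclose(table["msd_mean"], 5.0 * table["lag_h"] ** 2)

    def test_n_decreases_with_lag_for_varied_lengths(self):
        trajs = [traj_1d(np.zeros(20)), traj_1d(np.zeros(6))]
        table = population_msd(trajs, max_lag_h=15.0)
        n = table["n"].to_numpy()
        assert np.all(np.diff(n) <= 0)

    def test_summary_median_and_conventions(self):
        fits = [MotilityFit(D=d, v=1.0, f_D=0.5, residual=0.0, n_lags=5)
                for d in (1.0, 2.0, 3.0)]
        summary = summarize_population(fits)
        assert summary.median["D"] == 2.0
        assert summary.n == 3
        single = summarize_population(fits[:1])
        assert single.sd["D"] == 0.0
        assert single.single_fit

    def test_undefined_fits_excluded_from_fd(self):
        fits = [MotilityFit(D=1.0, v=1.0, f_D=0.4, residual=0.0, n_lags=5),
                MotilityFit(D=0.0, v=0.0, f_D=np.nan, residual=0.0, n_lags=5,
                            undefined=True)]
        summary = summarize_population(fits)
        assert summary.n_undefined == 1
        assert summary.median["f_D"] == pytest.approx(0.4)


class TestCompareFd:
    def test_identical_groups_degenerate(self):
        groups = {"a": [0.5] * 5, "b": [0.5] * 5}
        result = compare_fd(groups)
        assert result["kruskal"] == {"H": 0.0, "p": 1.0}

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(7)
        a = np.clip(rng.normal(0.30, 0.05, 25), 0, 1)   # directed-dominated
        b = np.clip(rng.normal(0.85, 0.05, 35), 0, 1)   # diffusion-dominated
        result = compare_fd({"directed": a, "diffusive": b})
        assert result["kruskal"]["p"] < 0.05
        assert result["dunn"]["p_adj"].iloc[0] < 0.05

    def test_dunn_adjusted_never_below_raw(self):
        rng = np.random.default_rng(9)
        groups = {k: rng.uniform(0, 1, 12) for k in "abc"}
        table = compare_fd(groups)["dunn"]
        assert np.all(table["p_adj"] >= table["p_raw"] - 1e-15)

    def test_group_size_validation(self):
        with pytest.raises(ValidationError):
            compare_fd({"a": [0.1, 0.2], "b": [0.3, 0.4, 0.5]})


class TestFitTrajectory:
    def test_recovers_directed_diffusive_mixture(self):
        rng = np.random.default_rng(3)
        d_axis, speed, dt = 1.0, 3.0, 0.1
        n_sub, n_frames = 10, 72
        direction = np.array([1.0, 0.0, 0.0])
        pos = [np.zeros(3)]
        for _ in range((n_frames - 1) * n_sub):
            step = rng.normal(0, np.sqrt(2 * d_axis * dt), 3) + speed * dt * direction
            pos.append(pos[-1] + step)
        pos = np.asarray(pos)[::n_sub]
        traj = Trajectory(0, np.arange(n_frames, dtype=float), pos)
        fit = fit_trajectory(traj)
        assert fit.n_lags == 25
        assert fit.v == pytest.approx(speed, rel=0.25)
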