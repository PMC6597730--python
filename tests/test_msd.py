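"""Time-averaged MSD estimator, ensemble statistics, and the propulsive fit."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from micromotor import (
    MSDCurve,
    Trajectory,
    compute_msd,
    ensemble_msd,
    fit_propulsive,
    simulate_ensemble,
    speed_summary,
)


def brute_force_msd(traj: Trajectory, k_max: int):
    """O(N^2) pairwise oracle: average over every (t, t + k dt) pair."""
    n = len(traj)
    out = []
    for k in range(1, k_max + 1):
        sq = []
        for t in range(n - k):
            dx = traj.x[t + k] - traj.x[t]
            dy = traj.y[t + k] - traj.y[t]
            sq.append(dx * dx + dy * dy)  # x*x is the exact IEEE square
        out.append(np.mean(np.array(sq)))
    return np.array(out)


def _random_walk(rng, n):
    steps = rng.standard_normal((2, n - 1)) * 0.1
    xy = np.concatenate([np.zeros((2, 1)), np.cumsum(steps, axis=1)], axis=1)
    return Trajectory(0, times=np.arange(n) * 0.04, x=xy[0], y=xy[1])


class TestComputeMsd:
    def test_hand_computed_line(self):
        tr = Trajectory(0, times=[0.0, 1.0, 2.0], x=[0.0, 1.0, 2.0], y=[0.0, 0.0, 0.0])
        curve = compute_msd(tr)
        assert curve.lags == pytest.approx([1.0, 2.0])
        assert curve.msd == pytest.approx([1.0, 4.0])
        assert list(curve.n_pairs) == [2, 1]

    def test_stationary_trajectory_zero(self):
        tr = Trajectory(0, times=np.arange(10) * 0.1, x=np.zeros(10), y=np.zeros(10))
        assert np.all(compute_msd(tr).msd == 0.0)

    def test_matches_brute_force_oracle_bit_exactly(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 200))
            tr = _random_walk(rng, n)
            k_max = n - 1
            curve = compute_msd(tr)
            oracle = brute_force_msd(tr, k_max)
            assert np.array_equal(curve.msd, oracle)

    def test_max_lag_truncates(self):
        tr = _random_walk(np.random.default_rng(0), 100)
        curve = compute_msd(tr, max_lag=0.4)
        assert curve.lags[-1] == pytest.approx(0.4)
        assert curve.lags.size == 10

    def test_excessive_max_lag_rejected(self):
        tr = _random_walk(np.random.default_rng(0), 50)
        with pytest.raises(ValueError):
            compute_msd(tr, max_lag=10.0)

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(0, times=[0.0], x=[0.0], y=[0.0])

    def test_non_uniform_times_rejected_with_location(self):
        with pytest.raises(ValueError, match="index 2"):
            Trajectory(0, times=[0.0, 0.1, 0.25, 0.35], x=np.zeros(4), y=np.zeros(4))


class TestEnsembleMsd:
    def test_identical_curves_zero_sem(self):
        tr = _random_walk(np.random.default_rng(1), 50)
        c = compute_msd(tr)
        ens = ensemble_msd([c, c])
        assert ens.msd == pytest.approx(c.msd)
        assert ens.sem == pytest.approx(np.zeros_like(c.msd))

    def test_hand_computed_mean_and_sem(self):
        lags = np.array([0.1])
        a = MSDCurve(lags=lags, msd=[1.0], n_pairs=[5])
        b = MSDCurve(lags=lags, msd=[3.0], n_pairs=[5])
        ens = ensemble_msd([a, b])
        assert ens.msd[0] == pytest.approx(2.0)
        assert ens.sem[0] == pytest.approx(1.0)  # sd sqrt(2) / sqrt(2)

    def test_single_curve_sem_undefined(self):
        tr = _random_walk(np.random.default_rng(2), 30)
        ens = ensemble_msd([compute_msd(tr)])
        assert ens.is_ensemble
        assert np.all(np.isnan(ens.sem))

    def test_length_mismatch_intersects_to_common_grid(self):
        rng = np.random.default_rng(3)
        long = compute_msd(_random_walk(rng, 80))
        short = compute_msd(_random_walk(rng, 40))
        ens = ensemble_msd([long, short])
        assert ens.lags.size == short.lags.size

    def test_incompatible_grids_rejected(self):
        a = MSDCurve(lags=[0.1, 0.2], msd=[1.0, 2.0], n_pairs=[5, 4])
        b = MSDCurve(lags=[0.15, 0.3], msd=[1.0, 2.0], n_pairs=[5, 4])
        with pytest.raises(ValueError):
            ensemble_msd([a, b])

    def test_twenty_brownian_particles_within_3_sem_of_line(self):
        d_t = 0.239
        trajs = simulate_ensemble(20, v=0.0, d_t=d_t, d_r=0.1792, fps=25, duration=30, seed=12)
        ens = ensemble_msd([compute_msd(tr, max_lag=2.0) for tr in trajs])
        z = (ens.msd - 4 * d_t * ens.lags) / ens.sem
        assert np.abs(z).max() < 3.0


class TestPropulsiveFit:
    def _curve(self, d_t, v, lags=None):
        lags = np.arange(1, 26) * 0.04 if lags is None else lags
        return MSDCurve(
            lags=lags, msd=4 * d_t * lags + v**2 * lags**2, n_pairs=np.full(lags.size, 100)
        )

    def test_exact_parabola_recovered(self):
        fit = fit_propulsive(self._curve(0.20, 1.50), tau_r=5.579, window_frac=0.2)
        assert fit.v == pytest.approx(1.50, abs=1e-9)
        assert fit.d_t == pytest.approx(0.20, abs=1e-9)
        assert fit.propulsive
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_line_gives_zero_speed(self):
        fit = fit_propulsive(self._curve(0.25, 0.0), tau_r=5.579, window_frac=0.2)
        assert fit.d_t == pytest.approx(0.25, abs=1e-9)
        assert fit.v == pytest.approx(0.0, abs=1e-6)

    def test_subdiffusive_curve_flagged_not_errored(self):
        lags = np.arange(1, 26) * 0.04
        msd = 4 * 0.2 * np.sqrt(lags)  # concave: fitted v^2 < 0
        fit = fit_propulsive(
            MSDCurve(lags=lags, msd=msd, n_pairs=np.full(lags.size, 50)), tau_r=5.579
        )
        assert not fit.propulsive
        assert fit.v == 0.0
        assert fit.v_squared < 0
        assert np.isnan(fit.v_se)

    def test_window_restricts_lags(self):
        fit = fit_propulsive(self._curve(0.2, 1.0), tau_r=5.579, window_frac=0.2)
        assert fit.fit_window_s <= 0.2 * 5.579
        assert fit.n_lags_used == 25  # 25 lags of 0.04 s all within 1.12 s

    def test_too_few_lags_rejected(self):
        lags = np.array([0.04, 0.08])
        curve = MSDCurve(lags=lags, msd=4 * 0.2 * lags, n_pairs=[9, 8])
        with pytest.raises(ValueError):
            fit_propulsive(curve, tau_r=5.579, window_frac=0.2)

    def test_delta_method_standard_error(self):
        # se_v = se_{v^2} / (2 v); check on a noisy parabola
        rng = np.random.default_rng(7)
        lags = np.arange(1, 26) * 0.04
        msd = 4 * 0.2 * lags + 2.0**2 * lags**2 + rng.normal(0, 0.002, lags.size)
        fit = fit_propulsive(
            MSDCurve(lags=lags, msd=msd, n_pairs=np.full(lags.size, 100)), tau_r=5.579
        )
        assert fit.v_se == pytest.approx(fit.v_squared_se / (2 * fit.v), rel=1e-12)

    @given(frac=st.floats(min_value=0.05, max_value=0.5))
    def test_noiseless_recovery_for_any_window(self, frac):
        fit = fit_propulsive(self._curve(0.3, 0.8), tau_r=5.579, window_frac=frac)
        assert fit.v == pytest.approx(0.8, abs=1e-8)


class TestSpeedSummary:
    def test_hand_computed_mean_sem(self):
        fits = []
        for v in (1.0, 3.0):
            curve = TestPropulsiveFit()._curve(0.2, v)
            fits.append(fit_propulsive(curve, tau_r=5.579))
        mean, sem = speed_summary(fits)
        assert mean == pytest.approx(2.0, abs=1e-8)
        assert sem == pytest.approx(1.0, abs=1e-8)

    def test_all_zero_speeds(self):
        curve = TestPropulsiveFit()._curve(0.2, 0.0)
        fits = [fit_propulsive(curve, tau_r=5.579) for _ in range(3)]
        mean, sem = speed_summary(fits)
        assert mean == pytest.approx(0.0, abs=1e-6)
        assert sem == pytest.approx(0.0, abs=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            speed_summary([])
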