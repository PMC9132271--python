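"""Weekly capture expectation, Poisson likelihood, and the annealer."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import aedespop as ap
from aedespop.calibration import LAMBDA_FLOOR, LikelihoodEvaluator
from aedespop.exceptions import CoverageError

from conftest import constant_env


def _traj_with_adults(a_values, start="2003-01-01"):
    dates = pd.date_range(start, periods=len(a_values), freq="D")
    return pd.DataFrame({"date": dates, "A": np.asarray(a_values, dtype=float)})


def _obs(year_weeks):
    return pd.DataFrame(
        [{"year": y, "week": w, "count": c} for y, w, c in year_weeks]
    )


class TestExpectedWeeklyCapture:
    def test_constant_adults(self):
        traj = _traj_with_adults(np.full(28, 100.0))
        obs = _obs([(2003, w, 0) for w in (1, 2, 3, 4)])
        lam = ap.expected_weekly_capture(traj, obs, 0.01)
        assert np.allclose(lam, 1.0)

    def test_floor_when_extinct(self):
        traj = _traj_with_adults(np.zeros(14))
        lam = ap.expected_weekly_capture(traj, _obs([(2003, 1, 0)]), 0.01)
        assert lam[0] == LAMBDA_FLOOR

    def test_sawtooth_matches_loop_oracle(self):
        a = np.arange(70, dtype=float) % 7  # sawtooth with known weekly mean 3
        traj = _traj_with_adults(a)
        obs = _obs([(2003, w, 0) for w in range(1, 11)])
        lam = ap.expected_weekly_capture(traj, obs, 0.5)
        for i, w in enumerate(range(1, 11)):
            days = a[(w - 1) * 7 : w * 7]
            assert lam[i] == pytest.approx(0.5 * days.mean())

    def test_uncovered_week_raises(self):
        traj = _traj_with_adults(np.ones(14))
        with pytest.raises(CoverageError):
            ap.expected_weekly_capture(traj, _obs([(2004, 1, 0)]), 0.01)


class TestPoissonLogLikelihood:
    def test_closed_forms(self):
        assert ap.poisson_log_likelihood([0], [1.0]) == pytest.approx(-1.0)
        assert ap.poisson_log_likelihood([2], [2.0]) == pytest.approx(np.log(2) - 2)

    def test_shared_lambda_maximized_at_mean(self):
        rng = np.random.default_rng(1)
        n = rng.poisson(4.0, size=40)
        grid = np.linspace(0.5, 10.0, 2000)
        lls = [ap.poisson_log_likelihood(n, np.full(len(n), g)) for g in grid]
        assert grid[int(np.argmax(lls))] == pytest.approx(n.mean(), abs=0.01)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ap.poisson_log_likelihood([-1], [1.0])
        with pytest.raises(ValueError):
            ap.poisson_log_likelihood([1], [0.0])
        with pytest.raises(ValueError):
            ap.poisson_log_likelihood([1, 2], [1.0])


class TestPeriodLogLikelihood:
    def test_full_range_equals_total_per_year(self):
        obs = _obs([(y, w, c) for y in (2003, 2004) for w, c in [(10, 1), (20, 3), (30, 2)]])
        lam = np.full(len(obs), 2.0)
        total = ap.poisson_log_likelihood(obs["count"], lam)
        per = ap.period_log_likelihood(obs, lam, [(1, 53)])
        assert per[(1, 53)] == pytest.approx(total / 2)

    def test_restriction_matches_direct_computation(self):
        obs = _obs([(2003, w, w % 3) for w in range(1, 53)])
        lam = np.linspace(0.5, 3.0, len(obs))
        per = ap.period_log_likelihood(obs, lam, [(16, 23), (29, 36)])
        for lo, hi in per:
            mask = obs["week"].between(lo, hi).to_numpy()
            assert per[(lo, hi)] == pytest.approx(
                ap.poisson_log_likelihood(obs["count"][mask], lam[mask])
            )

    def test_invalid_range_rejected(self):
        obs = _obs([(2003, 1, 0)])
        with pytest.raises(ValueError):
            ap.period_log_likelihood(obs, [1.0], [(0, 10)])


@pytest.fixture(scope="module")
def small_fit_setup(tokyo):
    weather = ap.generate_weather(ap.WeatherGenConfig(seed=21), 3)
    obs, truth = ap.generate_trap_counts(weather, ap.TrapGenConfig(seed=21))
    env = ap.build_environment(weather, tokyo)
    return env, obs, truth


class TestCalibrate:
    def test_zero_iteration_schedule_returns_start(self, small_fit_setup):
        env, obs, truth = small_fit_setup
        start = ap.ModelParams()
        cfg = ap.CalibrationConfig(n_levels=0, iters_per_level=0, seed=0)
        res = ap.calibrate(obs, env, start, cfg)
        assert res.params.diapause == start.diapause
        ev = LikelihoodEvaluator(env, obs, start)
        assert res.log_likelihood == pytest.approx(ev.loglik(start))

    def test_flat_surface_accepts_everything(self, small_fit_setup):
        env, obs, _ = small_fit_setup
        none = obs.iloc[:0]  # no observations: log-likelihood identically 0
        cfg = ap.CalibrationConfig(n_levels=2, iters_per_level=30, seed=4, initial_temp=1.0)
        res = ap.calibrate(none, env, ap.ModelParams(), cfg)
        assert res.log_likelihood == 0.0
        assert res.acceptance_rate.mean() > 0.9  # only bound rejections remain

    def test_reproducible_given_seed(self, small_fit_setup):
        env, obs, _ = small_fit_setup
        cfg = ap.CalibrationConfig(n_levels=3, iters_per_level=20, seed=9)
        r1 = ap.calibrate(obs, env, ap.ModelParams(), cfg)
        r2 = ap.calibrate(obs, env, ap.ModelParams(), cfg)
        assert r1.params == r2.params
        assert r1.log_likelihood == r2.log_likelihood
        assert np.array_equal(r1.loglik_trace, r2.loglik_trace)

    def test_best_trace_nondecreasing(self, small_fit_setup):
        env, obs, _ = small_fit_setup
        cfg = ap.CalibrationConfig(n_levels=5, iters_per_level=40, seed=2)
        res = ap.calibrate(obs, env, ap.ModelParams(), cfg)
        assert np.all(np.diff(res.best_trace) >= 0)
        assert res.log_likelihood == res.best_trace[-1]

    def test_evaluator_matches_reference_pipeline(self, small_fit_setup, params):
        """The fast evaluator agrees with the plain simulate ->
        expected_weekly_capture -> poisson_log_likelihood chain."""
        env, obs, _ = small_fit_setup
        ev = LikelihoodEvaluator(env, obs, params)
        traj = ap.simulate(env, params)
        lam = ap.expected_weekly_capture(traj, obs, params.capture_rate)
        ref = ap.poisson_log_likelihood(obs["count"], lam)
        assert ev.loglik(params) == pytest.approx(ref, rel=1e-12)
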