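"""Diapause gates, carrying capacity, stage ODEs and the integrator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import aedespop as ap
from aedespop.exceptions import InvalidCapacityError, NumericalInstabilityError
from aedespop.population import equilibrium_larvae

from conftest import constant_env

DIA = ap.DiapauseParams()


class TestDiapauseGates:
    def test_half_saturation_product(self):
        z1 = ap.diapause_induction_prob(DIA.beta_d1, DIA.beta_t1, -0.01, DIA)
        z2 = ap.diapause_termination_prob(DIA.beta_d2, DIA.beta_t2, +0.01, DIA)
        assert z1 == pytest.approx(0.25)
        assert z2 == pytest.approx(0.25)

    def test_photoperiod_trend_gating(self):
        # induction only while days shorten, termination only while they lengthen
        assert ap.diapause_induction_prob(10.0, 5.0, +0.01, DIA) == 0.0
        assert ap.diapause_induction_prob(10.0, 5.0, 0.0, DIA) == 0.0
        assert ap.diapause_termination_prob(16.0, 25.0, -0.01, DIA) == 0.0
        assert ap.diapause_termination_prob(16.0, 25.0, 0.0, DIA) == 0.0

    def test_saturated_limits(self):
        steep = dataclasses.replace(DIA, alpha_d1=1e2, alpha_t1=1e2, alpha_d2=1e2, alpha_t2=1e2)
        z1 = ap.diapause_induction_prob(steep.beta_d1 - 5, steep.beta_t1 - 10, -0.1, steep)
        z2 = ap.diapause_termination_prob(steep.beta_d2 + 5, steep.beta_t2 + 10, +0.1, steep)
        assert z1 == pytest.approx(1.0, abs=1e-6)
        assert z2 == pytest.approx(1.0, abs=1e-6)

    @settings(deadline=None, derandomize=True)
    @given(
        d_week=st.floats(0, 24),
        t_week=st.floats(-20, 45),
        delta_d=st.floats(-0.1, 0.1),
        log_alpha=st.floats(-1, 5.10),
    )
    def test_probabilities_bounded(self, d_week, t_week, delta_d, log_alpha):
        """z1, z2 in [0, 1] for any inputs, including the steepest fitted
        slopes (10^5.10), with no overflow."""
        p = dataclasses.replace(
            DIA,
            alpha_d1=10.0**log_alpha, alpha_t1=10.0**log_alpha,
            alpha_d2=10.0**log_alpha, alpha_t2=10.0**log_alpha,
        )
        z1 = ap.diapause_induction_prob(d_week, t_week, delta_d, p)
        z2 = ap.diapause_termination_prob(d_week, t_week, delta_d, p)
        assert 0.0 <= z1 <= 1.0 and 0.0 <= z2 <= 1.0

    def test_monotonicity_in_cues(self):
        grid = np.linspace(5, 20, 40)
        z1 = ap.diapause_induction_prob(grid, 15.0, -0.1, DIA)
        assert np.all(np.diff(z1) <= 1e-12)
        z2 = ap.diapause_termination_prob(grid, 15.0, +0.1, DIA)
        assert np.all(np.diff(z2) >= -1e-12)
        tgrid = np.linspace(0, 35, 40)
        assert np.all(np.diff(ap.diapause_induction_prob(12.0, tgrid, -0.1, DIA)) <= 1e-12)
        assert np.all(np.diff(ap.diapause_termination_prob(12.0, tgrid, +0.1, DIA)) >= -1e-12)


class TestThresholdDiapause:
    @pytest.mark.parametrize(
        "ta, d, expect_on, expect_off",
        [
            (20.0, 13.0, True, True),   # cool + short day -> induction (also past break cutoffs)
            (22.0, 13.0, False, True),  # induction temperature condition fails
            (11.0, 10.5, True, True),   # break conditions met (induction cutoffs too)
            (9.0, 10.0, True, False),   # too cold for break
        ],
    )
    def test_switches(self, ta, d, expect_on, expect_off):
        on, off = ap.threshold_diapause(ta, d)
        assert on is expect_on and off is expect_off


class TestCarryingCapacity:
    def test_full_bucket_gives_kappa_max(self):
        for nu in (0.0, 0.2, 0.5, 1.0, 2.0):
            p = ap.CarryingCapacityParams(kappa_max=123.0, nu=nu)
            assert ap.carrying_capacity(150.0, 150.0, p) == pytest.approx(123.0)

    def test_nu_zero_fixes_capacity(self):
        p = ap.CarryingCapacityParams(kappa_max=77.0, nu=0.0)
        for w in (0.0, 10.0, 149.9):
            assert ap.carrying_capacity(w, 150.0, p) == pytest.approx(77.0)

    def test_square_root_example(self):
        p = ap.CarryingCapacityParams(kappa_max=100.0, nu=0.5)
        assert ap.carrying_capacity(150.0 / 4, 150.0, p) == pytest.approx(50.0)

    def test_loglog_slope_recovers_nu(self):
        w = np.linspace(1.0, 150.0, 200)
        for nu in (0.2, 0.5, 1.0, 1.7):
            k = ap.carrying_capacity(w, 150.0, ap.CarryingCapacityParams(2000.0, nu))
            slope = np.polyfit(np.log(w / 150.0), np.log(k), 1)[0]
            assert slope == pytest.approx(nu, abs=1e-6)

    def test_floor_and_bounds(self):
        p = ap.CarryingCapacityParams(kappa_max=100.0, nu=1.0)
        assert ap.carrying_capacity(0.0, 150.0, p) == pytest.approx(1e-6)
        with pytest.raises(InvalidCapacityError):
            ap.carrying_capacity(151.0, 150.0, p)


class TestDerivatives:
    def test_extinction_absorbing(self, params):
        env = constant_env(1).iloc[0]
        rates = ap.derivatives(ap.PopulationState(), env, params)
        assert rates == (0.0, 0.0, 0.0, 0.0, 0.0)

    def test_full_diapause_routing(self, params):
        """With z1 = 1 all oviposition flows to the diapause pool."""
        env = constant_env(1, d_week=5.0, delta_d=-0.1).iloc[0]  # short, shortening days
        env = dict(env)
        env["ta_week"] = 5.0  # cold: induction sigmoid saturated
        state = ap.PopulationState(A=50.0)
        de, dedia, *_ = ap.derivatives(state, env, params)
        ov = params.thermal.o_v(env["t_air"])
        assert dedia == pytest.approx(ov * 50.0)
        assert de == pytest.approx(0.0)  # no active-egg inflow, E itself is 0

    def test_stage_flow_bookkeeping(self, params):
        """Sum of derivatives equals oviposition minus all mortality sinks:
        the development transfers cancel pairwise."""
        rng = np.random.default_rng(3)
        env = dict(constant_env(1, t_air=22.0, t_water=20.0).iloc[0])
        th = params.thermal
        for _ in range(50):
            s = ap.PopulationState(*rng.uniform(0, 1e4, size=5))
            rates = ap.derivatives(s, env, params)
            k = ap.carrying_capacity(env["soil_water"], env["w_star"], params.capacity)
            expected = (
                th.o_v(env["t_air"]) * s.A
                - th.m_E(env["t_water"]) * s.E
                - (th.m_L(env["t_water"]) + s.L / k) * s.L
                - th.m_P(env["t_water"]) * s.P
                - th.m_A(env["t_air"]) * s.A
            )
            assert sum(rates) == pytest.approx(expected, rel=1e-12)


class TestIntegration:
    def test_zero_state_stays_zero(self, params):
        env = constant_env(3)
        out = ap.step_population(ap.PopulationState(), env.iloc[0], params)
        assert out == ap.PopulationState()
        traj = ap.simulate(env, params, ap.PopulationState())
        assert (traj[["E", "E_dia", "L", "P", "A"]].to_numpy() == 0.0).all()

    def test_pure_death_drives_extinction(self, params):
        """With oviposition off the reproduction loop is broken: the total
        population (whose only remaining flows are mortality sinks) decays
        monotonically to zero, and the inflow-free egg stage decays
        monotonically stage-wise."""
        p = dataclasses.replace(
            params, thermal=dataclasses.replace(params.thermal, o_v=ap.QuadraticCurve(0.0, 10.0, 40.0))
        )
        env = constant_env(200)
        traj = ap.simulate(env, p, ap.PopulationState(E=100.0, L=100.0, P=100.0, A=100.0))
        total = traj[["E", "L", "P", "A"]].sum(axis=1).to_numpy()
        assert np.all(np.diff(total) <= 1e-9)
        assert np.all(np.diff(traj["E"].to_numpy()) <= 1e-9)
        assert traj[["E", "L", "P", "A"]].iloc[-1].max() < 1e-3

    def test_instability_is_reported(self, params):
        env = constant_env(5, soil_frac=1.0)
        huge = ap.PopulationState(L=1e300)
        with pytest.raises(NumericalInstabilityError):
            ap.simulate(env, params, huge)

    def test_simulate_deterministic(self, env3, params):
        t1 = ap.simulate(env3, params)
        t2 = ap.simulate(env3, params)
        pd.testing.assert_frame_equal(t1, t2)

    def test_larval_equilibrium_matches_closed_form(self, params):
        """Constant benign environment: the simulated larval plateau
        matches the analytic equilibrium with the crowding term active."""
        row = dict(constant_env(1, t_air=17.0, t_water=17.0).iloc[0])
        l_star = equilibrium_larvae(row, params)
        assert l_star > 0
        env = constant_env(4000, t_air=17.0, t_water=17.0)
        traj = ap.simulate(env, params, ap.PopulationState(E=10.0, L=10.0), dt=0.1)
        assert traj["L"].iloc[-1] == pytest.approx(l_star, rel=5e-3)
        # crowding genuinely active at the plateau
        assert l_star / traj["K"].iloc[-1] > 0.01

    def test_capacity_scaling_monotone(self, env3, params):
        """Doubling kappa_max never lowers the annual adult peak."""
        p2 = dataclasses.replace(
            params, capacity=dataclasses.replace(params.capacity, kappa_max=2 * params.capacity.kappa_max)
        )
        peak1 = ap.simulate(env3, params)["A"].max()
        peak2 = ap.simulate(env3, p2)["A"].max()
        assert peak2 >= peak1

    def test_approaches_annual_cycle_under_periodic_forcing(self, tokyo, params):
        """Ten years of periodic weather: year 10 repeats year 9."""
        w1 = ap.generate_weather(ap.WeatherGenConfig(seed=5), 1)
        dates = pd.date_range("2001-01-01", periods=3652, freq="D")
        doy = np.minimum(dates.dayofyear, 365) - 1
        wp = pd.DataFrame({k: w1[k].to_numpy()[doy] for k in w1.columns if k != "date"})
        wp.insert(0, "date", dates)
        traj = ap.simulate(ap.build_environment(wp, tokyo), params)
        yr = pd.DatetimeIndex(traj["date"]).year
        p9 = traj["A"][yr == 2009].max()
        p10 = traj["A"][yr == 2010].max()
        assert abs(p10 - p9) / p9 < 0.01

    def test_long_run_stays_finite_and_nonnegative(self, tokyo, params):
        w = ap.generate_weather(ap.WeatherGenConfig(seed=3), 100)
        traj = ap.simulate(ap.build_environment(w, tokyo), params)
        states = traj[["E", "E_dia", "L", "P", "A"]].to_numpy()
        assert np.isfinite(states).all()
        assert states.min() >= 0.0
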