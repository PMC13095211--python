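"""Dyadic coordination models: minimum-jerk references, duration
sensitivity, co-activity LQR, the deterministic-equivalent stochastic cost,
and the interactive-adaptation free-time solver."""

import numpy as np
import pytest

from dyadvigor import (CouplingParams,
                       InteractiveAdaptationConfig, SlowPartnerDistribution,
                       WristDynamics, duration_sensitivity, expected_cost,
                       minimum_jerk, monte_carlo_expected_cost,
                       predict_all_conditions, sensitivity_fast_cost_of_time,
                       simulate_co_activity, solve_free_time_oc,
                       solve_interactive_adaptation)
from dyadvigor.dyad_models import _ia_inner_solve, _uncertainty_integral
from dyadvigor.kinematics import AmplitudeDurationFit
from dyadvigor.params import (AD_LAW_FAST, AD_LAW_SLOW, COST_OF_TIME_FAST,
                              TARGET_AMPLITUDES_RAD)
from dyadvigor.solo_oc import CostOfTime


@pytest.fixture
def fit_fast():
    return AmplitudeDurationFit(*AD_LAW_FAST, r_squared=1.0, n_points=5)


@pytest.fixture
def fit_slow():
    return AmplitudeDurationFit(*AD_LAW_SLOW, r_squared=1.0, n_points=5)


@pytest.fixture
def slow_dist():
    return SlowPartnerDistribution()


@pytest.fixture
def ia_cfg(G_fast):
    return InteractiveAdaptationConfig(fast_cost_of_time=G_fast)


class TestMinimumJerk:
    def test_midpoint_velocity_closed_form(self):
        A, xi = 1.0, 0.8
        _, v = minimum_jerk(0.2, A, xi, xi / 2)
        assert float(v) == pytest.approx(1.875 * A / xi, rel=1e-12)

    def test_hold_extension_beyond_duration(self):
        q, v = minimum_jerk(0.2, 1.0, 0.8, 1.2)
        assert float(q) == pytest.approx(1.2)
        assert float(v) == 0.0

    def test_velocity_integrates_to_displacement(self):
        A, xi = 0.9, 0.6
        t = np.linspace(0, xi, 20001)
        _, v = minimum_jerk(0.0, A, xi, t)
        assert np.trapezoid(v, t) == pytest.approx(A, abs=1e-6)


class TestDurationSensitivity:
    def test_matches_central_finite_differences(self):
        A, mu = 1.2, 0.7
        t = np.linspace(0.02, mu - 0.02, 101)
        h = 1e-6
        _, v_plus = minimum_jerk(0.0, A, mu + h, t)
        _, v_minus = minimum_jerk(0.0, A, mu - h, t)
        fd = (v_plus - v_minus) / (2 * h)
        analytic = duration_sensitivity(0.0, A, mu, t)
        np.testing.assert_allclose(analytic, fd, rtol=1e-6)

    def test_zero_at_movement_endpoints_and_beyond(self):
        A, mu = 1.0, 0.5
        assert duration_sensitivity(0.0, A, mu, 0.0) == 0.0
        assert duration_sensitivity(0.0, A, mu, mu) == 0.0
        assert duration_sensitivity(0.0, A, mu, 1.5 * mu) == 0.0

    def test_negative_at_mid_movement(self):
        # shortening the duration speeds the movement up at its middle
        assert duration_sensitivity(0.0, 1.0, 0.6, 0.3) < 0.0


class TestCoActivity:
    def test_identical_plans_transmit_no_torque(self, fit_fast):
        pred = simulate_co_activity(fit_fast, fit_fast,
                                    CouplingParams(stiffness=0.5), 5)
        assert pred.mean_abs_tau_i < 1e-4

    def test_largest_target_low_stiffness_torque(self, fit_fast, fit_slow):
        pred = simulate_co_activity(fit_fast, fit_slow,
                                    CouplingParams(stiffness=0.5), 5)
        assert pred.mean_abs_tau_i == pytest.approx(0.1, rel=0.25)

    def test_largest_target_high_stiffness_torque(self, fit_fast, fit_slow):
        pred = simulate_co_activity(fit_fast, fit_slow,
                                    CouplingParams(stiffness=1.6), 5)
        assert pred.mean_abs_tau_i == pytest.approx(0.23, rel=0.25)

    def test_torque_grows_with_vigor_gap(self, fit_fast):
        gaps = np.linspace(0.0, 0.115, 5)
        torques = []
        for g in gaps:
            slow = AmplitudeDurationFit(AD_LAW_FAST[0] + g, AD_LAW_FAST[1],
                                        r_squared=1.0, n_points=5)
            torques.append(simulate_co_activity(
                fit_fast, slow, CouplingParams(stiffness=0.5), 5).mean_abs_tau_i)
        assert np.all(np.diff(torques) > 0)


class TestExpectedCost:
    @staticmethod
    def _optimal_control(T, mu, A, dyn, effort, kappa, q_tau):
        inner = _ia_inner_solve(T, A, mu, dyn, effort, kappa, q_tau)
        return inner.u, inner.cost

    def test_zero_coupling_reduces_to_solo_cost(self, dyn, effort, ia_cfg,
                                                slow_dist, G_fast):
        A, mu, _ = slow_dist.target(3)
        T = 0.6
        u, _ = self._optimal_control(T, mu, A, dyn, effort, 0.0, ia_cfg.q_tau)
        total = expected_cost(u, T, ia_cfg, slow_dist,
                              CouplingParams(stiffness=0.0), dyn, effort, 3)
        # integrate the same control through the uncoupled dynamics
        t = np.linspace(0, T, u.size)
        x = np.zeros(3)
        X = np.zeros((u.size, 3))
        I, Dv = dyn.inertia, dyn.damping + dyn.viscosity
        for i in range(u.size - 1):
            dt = t[1] - t[0]
            x = x + dt * np.array([x[1], (x[2] - Dv * x[1]) / I, u[i]])
            X[i + 1] = x
        w_q = effort.q_weight(A)
        solo = (np.trapezoid(w_q * (X[:, 0] - A) ** 2
                             + effort.torque_change_weight * u ** 2, t)
                + float(G_fast.value(T)))
        assert total == pytest.approx(solo, rel=1e-9)

    def test_zero_sigma_removes_uncertainty_term(self, dyn, effort, ia_cfg):
        dist0 = SlowPartnerDistribution(sigma=(0.0,) * 5)
        dist1 = SlowPartnerDistribution()
        A, mu, sigma = dist1.target(5)
        T = 0.7
        kappa = 0.5
        u, _ = self._optimal_control(T, mu, A, dyn, effort, kappa, ia_cfg.q_tau)
        coupling = CouplingParams(stiffness=kappa)
        c0 = expected_cost(u, T, ia_cfg, dist0, coupling, dyn, effort, 5)
        c1 = expected_cost(u, T, ia_cfg, dist1, coupling, dyn, effort, 5)
        gap = _uncertainty_integral(A, mu, sigma, ia_cfg.q_tau, kappa, T)
        assert c1 - c0 == pytest.approx(gap, rel=1e-9)
        assert gap > 0

    def test_monte_carlo_matches_deterministic_equivalent(self, dyn, effort,
                                                          ia_cfg):
        """10^4-sample Monte-Carlo of the stochastic cost agrees with the
        closed form within the first-order linearization bound at
        sigma/mu = 0.1."""
        A = TARGET_AMPLITUDES_RAD[2]
        mu = AD_LAW_SLOW[0] * A + AD_LAW_SLOW[1]
        dist = SlowPartnerDistribution(
            amplitudes=TARGET_AMPLITUDES_RAD,
            mu=tuple(AD_LAW_SLOW[0] * a + AD_LAW_SLOW[1]
                     for a in TARGET_AMPLITUDES_RAD),
            sigma=tuple(0.1 * (AD_LAW_SLOW[0] * a + AD_LAW_SLOW[1])
                        for a in TARGET_AMPLITUDES_RAD))
        T = 0.65
        kappa = 0.5
        u, _ = self._optimal_control(T, mu, A, dyn, effort, kappa, ia_cfg.q_tau)
        coupling = CouplingParams(stiffness=kappa)
        det = expected_cost(u, T, ia_cfg, dist, coupling, dyn, effort, 3)
        mc = monte_carlo_expected_cost(u, T, ia_cfg, dist, coupling, dyn,
                                       effort, 3, n_samples=10_000,
                                       rng=np.random.default_rng(0))
        assert mc == pytest.approx(det, rel=0.05)

    def test_uncertainty_integral_nondecreasing_in_horizon(self, ia_cfg,
                                                           slow_dist):
        A, mu, sigma = slow_dist.target(4)
        Ts = np.linspace(0.1, 1.5, 15)
        vals = [_uncertainty_integral(A, mu, sigma, ia_cfg.q_tau, 0.5, T)
                for T in Ts]
        assert np.all(np.diff(vals) >= -1e-15)


class TestInteractiveAdaptation:
    def test_vanishing_coupling_recovers_solo_fast_prediction(
            self, dyn, effort, G_fast, slow_dist):
        """With kappa -> 0 the dyad plan equals the fast solo plan to 2 ms."""
        cfg = InteractiveAdaptationConfig(fast_cost_of_time=G_fast)
        pred = solve_interactive_adaptation(
            cfg, slow_dist, CouplingParams(stiffness=1e-9), dyn=dyn,
            effort=effort, target_index=2)
        solo = solve_free_time_oc(dyn, effort, G_fast,
                                  TARGET_AMPLITUDES_RAD[1])
        assert abs(pred.predicted_T - solo.duration) <= 2e-3

    def test_faster_slow_partner_speeds_up_the_dyad(self, ia_cfg):
        """Scaling every mu_k down drags the predicted duration down."""
        coupling = CouplingParams(stiffness=0.5)
        durations = []
        # stay in the regime where the slow partner is the slower one
        for scale in (1.0, 0.9, 0.8):
            mu = tuple(scale * (AD_LAW_SLOW[0] * A + AD_LAW_SLOW[1])
                       for A in TARGET_AMPLITUDES_RAD)
            dist = SlowPartnerDistribution(mu=mu)
            pred = solve_interactive_adaptation(ia_cfg, dist, coupling,
                                                target_index=4)
            durations.append(pred.predicted_T)
        assert durations[0] > durations[1] > durations[2]

    def test_no_load_dyad_faster_than_fast_leader_for_far_targets(
            self, ia_cfg, dyn, effort, G_fast):
        dist = SlowPartnerDistribution()
        coupling = CouplingParams(stiffness=0.5)
        for k in (4, 5):
            pred = solve_interactive_adaptation(ia_cfg, dist, coupling,
                                                target_index=k)
            solo = solve_free_time_oc(dyn, effort, G_fast,
                                      TARGET_AMPLITUDES_RAD[k - 1])
            assert pred.predicted_T < solo.duration

    def test_scale_one_gives_zero_sensitivity(self, ia_cfg, slow_dist):
        out = sensitivity_fast_cost_of_time(
            ia_cfg, slow_dist, CouplingParams(stiffness=0.5), scale=1.0,
            target_indices=(1,))
        assert out[1] == 0.0


class TestPredictAllConditions:
    @pytest.fixture(scope="class")
    @staticmethod
    def table():
        G_fast = CostOfTime(*COST_OF_TIME_FAST)
        fit_f = AmplitudeDurationFit(*AD_LAW_FAST, r_squared=1.0, n_points=5)
        fit_s = AmplitudeDurationFit(*AD_LAW_SLOW, r_squared=1.0, n_points=5)
        return predict_all_conditions(G_fast, None, fit_f, fit_s,
                                      viscosities=(0.0,),
                                      stiffnesses=(0.5,))

    def test_condition_enumeration_complete(self, table):
        for hyp in ("co_activity", "leader_fast", "leader_slow", "weighted",
                    "interactive_adaptation"):
            rows = [p for p in table if p.hypothesis == hyp]
            assert len(rows) == 5  # 5 targets x 1 kappa x 1 nu

    def test_leader_fast_rows_equal_fast_solo_durations(self, table, dyn,
                                                        effort):
        G_fast = CostOfTime(*COST_OF_TIME_FAST)
        for p in table:
            if p.hypothesis == "leader_fast":
                sol = solve_free_time_oc(dyn, effort, G_fast,
                                         TARGET_AMPLITUDES_RAD[p.target_index - 1])
                assert p.predicted_T == pytest.approx(sol.duration, abs=1e-9)

    def test_interactive_adaptation_beats_fast_leader_for_far_targets(self, table):
        ia = {p.target_index: p.predicted_T for p in table
              if p.hypothesis == "interactive_adaptation"}
        lf = {p.target_index: p.predicted_T for p in table
              if p.hypothesis == "leader_fast"}
        for k in (3, 4, 5):
            assert ia[k] < lf[k]
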