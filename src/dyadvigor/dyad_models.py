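"""Forward models of the four dyadic coordination hypotheses.

The coupled task: two wrists joined by a virtual elastic band of stiffness
kappa exchange the interaction torque tau_i = kappa (q_f - q_s).  Four
hypotheses about how the partners combine their motor plans are simulated:

* co-activity -- each partner tracks their own minimum-jerk plan (durations
  from their solo amplitude-duration laws) through a finite-horizon LQR on
  the coupled dynamics; the hypothesis is scored by the interaction torque
  it predicts.
* leader-follower -- the dyad adopts one partner's solo plan wholesale
  (fast-lead or slow-lead baselines).
* weighted adaptation -- a convex combination of the two solo plans.
* interactive adaptation -- the dyad plans a single control minimizing the
  fast partner's solo cost (effort + cost of time) plus the expected
  variation of the interaction torque against a distribution of slow-partner
  minimum-jerk trajectories of uncertain duration xi ~ (mu_k, sigma_k).
  Linearizing the slow velocity in xi about mu and dropping cross-covariance
  terms gives a deterministic-equivalent cost; with the coupling torque in
  the fast dynamics the inner fixed-horizon problem stays linear-quadratic
  and the free final time is found by the same outer search as the solo
  model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import params
from ._collocation import default_node_count, solve_lq_fixed_time
from ._lqr import coupled_matrices, simulate_tracking
from .kinematics import AmplitudeDurationFit
from .solo_oc import (CostOfTime, EffortCostParams, WristDynamics,
                      _outer_duration_search)

__all__ = [
    "CouplingParams", "SlowPartnerDistribution", "InteractiveAdaptationConfig",
    "DyadPrediction", "minimum_jerk", "duration_sensitivity",
    "simulate_co_activity", "expected_cost", "monte_carlo_expected_cost",
    "solve_interactive_adaptation", "sensitivity_fast_cost_of_time",
    "predict_all_conditions",
]

HYPOTHESES = ("co_activity", "leader_fast", "leader_slow", "weighted",
              "interactive_adaptation")


@dataclass(frozen=True)
class CouplingParams:
    """Elastic coupling stiffness and shared viscous load."""

    stiffness: float            # Nm/rad
    viscosity: float = 0.0      # Nm s/rad

    def __post_init__(self):
        if self.stiffness < 0 or self.viscosity < 0:
            raise ValueError("coupling parameters must be nonnegative")


@dataclass(frozen=True)
class SlowPartnerDistribution:
    """Distribution of the slow partner's minimum-jerk plans per target.

    ``mu`` and ``sigma`` are per-target means and standard deviations of the
    movement duration xi; amplitudes are the target set.  No distributional
    shape is assumed beyond (mu, sigma) for the deterministic-equivalent
    cost; sampling oracles use a truncated normal (support > 0.05 s).
    """

    amplitudes: tuple = params.TARGET_AMPLITUDES_RAD
    mu: tuple = tuple(params.AD_LAW_SLOW[0] * A + params.AD_LAW_SLOW[1]
                      for A in params.TARGET_AMPLITUDES_RAD)
    sigma: tuple = tuple(params.sigma_schedule("none"))
    q0: float = 0.0

    def __post_init__(self):
        if not (len(self.amplitudes) == len(self.mu) == len(self.sigma)):
            raise ValueError("amplitudes, mu and sigma must have equal length")
        if min(self.mu) <= 0 or min(self.sigma) < 0:
            raise ValueError("mu must be positive and sigma nonnegative")
        if np.any(np.diff(self.mu) <= 0):
            raise ValueError("mu must increase with amplitude")

    def target(self, target_index: int):
        """(amplitude, mu, sigma) for a 1-based target index."""
        i = target_index - 1
        return self.amplitudes[i], self.mu[i], self.sigma[i]


@dataclass(frozen=True)
class InteractiveAdaptationConfig:
    """Weights and uncertainty model of the interactive-adaptation cost."""

    fast_cost_of_time: CostOfTime
    q_tau: float = params.Q_TAU
    process_noise: float = 0.0      # (Nm/s)^2 s intensity on the torque channel

    def __post_init__(self):
        if self.q_tau < 0 or self.process_noise < 0:
            raise ValueError("weights must be nonnegative")


@dataclass
class DyadPrediction:
    """Per-condition, per-target prediction of one coordination hypothesis."""

    hypothesis: str
    condition: str
    target_index: int
    predicted_T: float
    mean_abs_tau_i: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.predicted_T > 0:
            raise ValueError("predicted duration must be positive")
        if self.mean_abs_tau_i is not None and self.mean_abs_tau_i < 0:
            raise ValueError("mean absolute torque must be nonnegative")


# ---------------------------------------------------------------------------
# minimum-jerk reference family and its duration sensitivity

def minimum_jerk(q0: float, amplitude: float, xi: float, t):
    """Quintic minimum-jerk position and velocity, held at the target after xi."""
    if xi <= 0:
        raise ValueError("duration must be positive")
    t = np.asarray(t, float)
    z = np.clip(t / xi, 0.0, 1.0)
    pos = q0 + amplitude * z ** 3 * (10.0 - 15.0 * z + 6.0 * z ** 2)
    vel = (amplitude / xi) * 30.0 * z ** 2 * (1.0 - z) ** 2
    vel = np.where((t < 0) | (t >= xi), 0.0, vel)
    return pos, vel


def duration_sensitivity(q0: float, amplitude: float, mu: float, t):
    """Analytic d(velocity)/d(duration) of the minimum-jerk family at xi = mu.

    With v(t; xi) = (A/xi) w(t/xi), w(z) = 30 z^2 (1-z)^2, the partial is
    -(A/mu^2) [w(z) + z w'(z)] for t in [0, mu] and 0 for t > mu (the held
    trajectory does not move).  ``q0`` is accepted for interface symmetry.
    """
    if mu <= 0:
        raise ValueError("mean duration must be positive")
    t = np.asarray(t, float)
    z = np.clip(t / mu, 0.0, 1.0)
    w = 30.0 * z ** 2 * (1.0 - z) ** 2
    wp = 60.0 * z - 180.0 * z ** 2 + 120.0 * z ** 3
    out = -(amplitude / mu ** 2) * (w + z * wp)
    return np.where((t < 0) | (t >= mu), 0.0, out)


# ---------------------------------------------------------------------------
# co-activity: independent plans tracked by LQR through the coupling

def simulate_co_activity(
    fit_f: AmplitudeDurationFit,
    fit_s: AmplitudeDurationFit,
    coupling: CouplingParams,
    target_index: int,
    amplitudes=params.TARGET_AMPLITUDES_RAD,
    q0: float = 0.0,
    dt: float = 1e-3,
    lqr_q: tuple = (100.0, 0.1, 100.0, 0.1),
) -> DyadPrediction:
    """Independent minimum-jerk plans tracked through the coupled dynamics.

    Each partner's reference has the duration of their own amplitude-duration
    law; the fast reference is held at the target once complete.  A
    finite-horizon time-varying LQR (state (q_f, qdot_f, q_s, qdot_s),
    Q = diag(100, 0.1, 100, 0.1), R = I) tracks the joint reference and the
    coupled dynamics are Euler-integrated at 1 kHz.  The prediction reports
    the mean absolute interaction torque over the slow partner's duration;
    the dyad's movement completes with the slow plan, so its duration is the
    slow partner's.
    """
    if coupling.stiffness <= 0:
        raise ValueError("co-activity simulation needs positive stiffness")
    A_amp = amplitudes[target_index - 1]
    T_f = float(fit_f.predict(A_amp))
    T_s = float(fit_s.predict(A_amp))
    horizon = max(T_f, T_s)
    n = int(np.ceil(horizon / dt)) + 1
    t = np.arange(n) * dt
    qf, vf = minimum_jerk(q0, A_amp, T_f, t)
    qs, vs = minimum_jerk(q0, A_amp, T_s, t)
    ref = np.stack([qf, vf, qs, vs], axis=1)
    A_sys, B_sys = coupled_matrices(coupling.stiffness, coupling.viscosity)
    try:
        traj = simulate_tracking(A_sys, B_sys, np.diag(lqr_q), np.eye(2), ref, dt,
                                 x0=np.array([q0, 0.0, q0, 0.0]))
        diverged = not np.all(np.isfinite(traj))
    except FloatingPointError:
        traj = np.full((n, 4), np.nan)
        diverged = True
    tau_i = coupling.stiffness * (traj[:, 0] - traj[:, 2])
    mask = t <= T_s
    mean_abs = float(np.mean(np.abs(tau_i[mask]))) if not diverged else float("nan")
    return DyadPrediction(
        hypothesis="co_activity",
        condition=_condition_label(coupling),
        target_index=target_index,
        predicted_T=T_s,
        mean_abs_tau_i=mean_abs,
        extras={"t": t, "trajectory": traj, "tau_i": tau_i,
                "T_fast": T_f, "T_slow": T_s, "diverged": diverged},
    )


def _condition_label(coupling: CouplingParams) -> str:
    k = "KL" if np.isclose(coupling.stiffness, 0.5) else (
        "KH" if np.isclose(coupling.stiffness, 1.6) else f"K{coupling.stiffness:g}")
    return k + {0.0: "", 0.075: "VL", 0.15: "VH"}.get(coupling.viscosity,
                                                      f"V{coupling.viscosity:g}")


# ---------------------------------------------------------------------------
# interactive adaptation: deterministic-equivalent stochastic planning

def _fast_state_matrices(dyn: WristDynamics, kappa: float):
    I = dyn.inertia
    Dv = dyn.damping + dyn.viscosity
    A_c = np.array([[0.0, 1.0, 0.0],
                    [-kappa / I, -Dv / I, 1.0 / I],
                    [0.0, 0.0, 0.0]])
    return A_c, np.array([0.0, 0.0, 1.0])


def _uncertainty_integral(amplitude, mu, sigma, q_tau, kappa, T, n=1500):
    """Q_tau kappa^2 sigma^2 int_0^T (dv_s/dxi|_mu)^2 dt (control-independent)."""
    upper = min(T, mu)
    tt = np.linspace(0.0, upper, n)
    s = duration_sensitivity(0.0, amplitude, mu, tt)
    return q_tau * kappa ** 2 * sigma ** 2 * float(np.trapezoid(s ** 2, tt))


def _process_noise_integral(cfg, dyn, kappa, q_tau, T, n=400):
    """Q_tau kappa^2 int P_qdot(t) dt with P propagated from torque-channel noise.

    The open-loop state covariance obeys Pdot = A P + P A' + L c L' with
    noise intensity c on the torque-change channel; zero intensity makes the
    term vanish identically.
    """
    if cfg.process_noise == 0.0:
        return 0.0
    A_c, b_c = _fast_state_matrices(dyn, kappa)
    L = np.outer(b_c, b_c) * cfg.process_noise
    tt = np.linspace(0.0, T, n)
    dt = tt[1] - tt[0]
    P = np.zeros((3, 3))
    acc = 0.0
    for _ in tt[1:]:
        P = P + dt * (A_c @ P + P @ A_c.T + L)
        acc += P[1, 1] * dt
    return q_tau * kappa ** 2 * acc


def _ia_inner_solve(T, amplitude, mu, dyn, effort, kappa, q_tau, q0=0.0,
                    n_nodes=None):
    """Fixed-horizon LQ solve of the deterministic-equivalent plan."""
    n_nodes = n_nodes or default_node_count(T)
    t = np.linspace(0.0, T, n_nodes + 1)
    q_ref, v_ref = minimum_jerk(q0, amplitude, mu, t)
    A_c, b_c = _fast_state_matrices(dyn, kappa)
    I = dyn.inertia
    q_e = q0 + amplitude
    w_q = effort.q_weight(amplitude)
    w_v = q_tau * kappa ** 2
    forcing = np.zeros((n_nodes + 1, 3))
    forcing[:, 1] = kappa * q_ref / I
    ref = np.column_stack([np.full_like(t, q_e), v_ref, np.zeros_like(t)])
    tau0 = kappa * (q0 - q_ref[0])
    tauT = kappa * (q_e - q_ref[-1])
    return solve_lq_fixed_time(
        T=T, A_c=A_c, b_c=b_c,
        x0=np.array([q0, 0.0, tau0]), xT=np.array([q_e, 0.0, tauT]),
        state_weight=np.array([w_q, w_v, 0.0]), u_weight=effort.torque_change_weight,
        state_ref=ref, forcing=forcing, n_nodes=n_nodes,
    )


def expected_cost(u, T, cfg: InteractiveAdaptationConfig,
                  slow: SlowPartnerDistribution, coupling: CouplingParams,
                  dyn: WristDynamics, effort: EffortCostParams,
                  target_index: int, q0: float | None = None) -> float:
    """Deterministic-equivalent dyad cost of a given open-loop control.

    Evaluates the fast partner's solo cost (effort + cost of time at T) plus
    the interaction-torque-variation terms -- expected tracking error against
    the mean slow plan, the sigma^2-weighted duration-uncertainty term, and
    the optional process-noise velocity-covariance term -- by integrating the
    mean dynamics under ``u`` (Euler on the sample grid of ``u``).
    """
    A_amp, mu, sigma = slow.target(target_index)
    q0 = slow.q0 if q0 is None else q0
    kappa = coupling.stiffness
    u = np.asarray(u, float)
    n = u.size
    t = np.linspace(0.0, T, n)
    dt = t[1] - t[0]
    q_ref, v_ref = minimum_jerk(q0, A_amp, mu, t)
    A_c, b_c = _fast_state_matrices(dyn, kappa)
    I = dyn.inertia
    x = np.array([q0, 0.0, kappa * (q0 - q_ref[0])])
    X = np.zeros((n, 3))
    X[0] = x
    for i in range(n - 1):
        forcing = np.array([0.0, kappa * q_ref[i] / I, 0.0])
        x = x + dt * (A_c @ x + b_c * u[i] + forcing)
        X[i + 1] = x
    q_e = q0 + A_amp
    w_q = effort.q_weight(A_amp)
    beta = effort.torque_change_weight
    effort_term = float(np.trapezoid(w_q * (X[:, 0] - q_e) ** 2 + beta * u ** 2, t))
    tracking = cfg.q_tau * kappa ** 2 * float(np.trapezoid((X[:, 1] - v_ref) ** 2, t))
    unc = _uncertainty_integral(A_amp, mu, sigma, cfg.q_tau, kappa, T)
    pn = _process_noise_integral(cfg, dyn, kappa, cfg.q_tau, T)
    time_cost = float(cfg.fast_cost_of_time.value(T))
    return effort_term + time_cost + tracking + unc + pn


def monte_carlo_expected_cost(u, T, cfg, slow, coupling, dyn, effort,
                              target_index, n_samples: int = 10_000,
                              rng=None, q0: float | None = None) -> float:
    """Sampling oracle for the stochastic dyad cost.

    Draws slow durations xi from a truncated normal (support > 0.05 s),
    integrates the fast dynamics against each sampled slow trajectory under
    the same open-loop control, and averages the exact per-sample cost with
    the linearized interaction-torque-variation integrand.  Agrees with
    `expected_cost` (process noise off) to first order in sigma/mu.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    A_amp, mu, sigma = slow.target(target_index)
    q0 = slow.q0 if q0 is None else q0
    kappa = coupling.stiffness
    u = np.asarray(u, float)
    n = u.size
    t = np.linspace(0.0, T, n)
    dt = t[1] - t[0]
    A_c, b_c = _fast_state_matrices(dyn, kappa)
    I = dyn.inertia
    q_e = q0 + A_amp
    w_q = effort.q_weight(A_amp)
    beta = effort.torque_change_weight
    _, v_ref_mu = minimum_jerk(q0, A_amp, mu, t)
    s_mu = duration_sensitivity(q0, A_amp, mu, t)
    time_cost = float(cfg.fast_cost_of_time.value(T))

    xi = rng.normal(mu, sigma, size=n_samples)
    while np.any(xi <= 0.05):
        bad = xi <= 0.05
        xi[bad] = rng.normal(mu, sigma, size=int(bad.sum()))

    total = 0.0
    for x_dur in xi:
        q_ref, _ = minimum_jerk(q0, A_amp, float(x_dur), t)
        x = np.array([q0, 0.0, kappa * (q0 - q_ref[0])])
        X = np.zeros((n, 3))
        X[0] = x
        for i in range(n - 1):
            forcing = np.array([0.0, kappa * q_ref[i] / I, 0.0])
            x = x + dt * (A_c @ x + b_c * u[i] + forcing)
            X[i + 1] = x
        eff = float(np.trapezoid(w_q * (X[:, 0] - q_e) ** 2 + beta * u ** 2, t))
        torque_var = cfg.q_tau * kappa ** 2 * float(np.trapezoid(
            (X[:, 1] - v_ref_mu) ** 2 + (s_mu * (x_dur - mu)) ** 2, t))
        total += eff + time_cost + torque_var
    return total / n_samples


def solve_interactive_adaptation(
    cfg: InteractiveAdaptationConfig,
    slow: SlowPartnerDistribution,
    coupling: CouplingParams,
    dyn: WristDynamics | None = None,
    effort: EffortCostParams | None = None,
    target_index: int = 1,
    t_bounds: tuple[float, float] = (0.01, 10.0),
    n_grid: int = 48,
    xatol: float = 5e-5,
    degeneracy_rtol: float = 0.01,
) -> DyadPrediction:
    """Free-final-time minimization of the deterministic-equivalent dyad cost.

    Inner fixed-horizon solves are exact LQ collocation solves; the outer
    duration search uses a log-spaced coarse grid with bounded refinement of
    every grid-local minimum and returns the smallest near-optimal duration
    (same convention as the solo free-time solver).
    """
    dyn = dyn or WristDynamics(viscosity=coupling.viscosity)
    effort = effort or EffortCostParams()
    A_amp, mu, sigma = slow.target(target_index)
    kappa = coupling.stiffness
    G = cfg.fast_cost_of_time

    def objective(T):
        inner = _ia_inner_solve(T, A_amp, mu, dyn, effort, kappa, cfg.q_tau,
                                q0=slow.q0)
        return (inner.cost + float(G.value(T))
                + _uncertainty_integral(A_amp, mu, sigma, cfg.q_tau, kappa, T)
                + _process_noise_integral(cfg, dyn, kappa, cfg.q_tau, T))

    T_star, cands, multimodal = _outer_duration_search(
        objective, t_bounds, n_grid, xatol, degeneracy_rtol)
    best_val = min(v for _, v in cands)

    inner = _ia_inner_solve(T_star, A_amp, mu, dyn, effort, kappa, cfg.q_tau,
                            q0=slow.q0)
    if not inner.converged:
        warnings.warn("interactive-adaptation inner solve did not converge")
    q_ref, _ = minimum_jerk(slow.q0, A_amp, mu, inner.t)
    tau_i = kappa * (inner.x[:, 0] - q_ref)
    return DyadPrediction(
        hypothesis="interactive_adaptation",
        condition=_condition_label(coupling),
        target_index=target_index,
        predicted_T=T_star,
        mean_abs_tau_i=float(np.mean(np.abs(tau_i))),
        extras={
            "t": inner.t, "q": inner.x[:, 0], "qdot": inner.x[:, 1],
            "tau": inner.x[:, 2], "u": inner.u, "tau_i": tau_i,
            "total_cost": best_val, "multimodal": multimodal,
            "mu": mu, "sigma": sigma, "converged": inner.converged,
        },
    )


def sensitivity_fast_cost_of_time(
    cfg: InteractiveAdaptationConfig,
    slow: SlowPartnerDistribution,
    coupling: CouplingParams,
    scale: float,
    target_indices=(1, 2, 3, 4, 5),
    **solver_kwargs,
):
    """|Delta T| per target when the fast cost of time is scaled by ``scale``.

    Re-solves interactive adaptation with p1 -> scale * p1 and reports the
    absolute change of the optimal duration against the unscaled baseline.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    out = {}
    for k in target_indices:
        base = solve_interactive_adaptation(cfg, slow, coupling,
                                            target_index=k, **solver_kwargs)
        if scale == 1.0:
            out[k] = 0.0
            continue
        scaled_cfg = InteractiveAdaptationConfig(
            fast_cost_of_time=cfg.fast_cost_of_time.scaled(scale),
            q_tau=cfg.q_tau, process_noise=cfg.process_noise)
        alt = solve_interactive_adaptation(scaled_cfg, slow, coupling,
                                           target_index=k, **solver_kwargs)
        out[k] = abs(alt.predicted_T - base.predicted_T)
    return out


# ---------------------------------------------------------------------------
# all-condition prediction table

def predict_all_conditions(
    G_fast: CostOfTime,
    G_slow: CostOfTime | None,
    fit_f: AmplitudeDurationFit,
    fit_s: AmplitudeDurationFit,
    alpha: float = 0.5,
    q_tau: float = params.Q_TAU,
    amplitudes=params.TARGET_AMPLITUDES_RAD,
    stiffnesses=(0.5, 1.6),
    viscosities=params.VISCOUS_LOADS,
    hypotheses=HYPOTHESES,
    effort: EffortCostParams | None = None,
    slow_baseline: str = "law",
    solo_solver=None,
):
    """One DyadPrediction per hypothesis per condition (5 targets x 2 kappa x
    3 nu = 30 conditions).

    The fast-leader baseline is the fast solo free-final-time duration under
    each load.  Slow-partner durations (the slow-leader baseline and the
    interactive-adaptation mu_k) come from the slow amplitude-duration law,
    inflated per load level on the forward model's stable branch
    (``slow_baseline='law'``, the default: the slow plan family is defined
    by the group's empirical law); ``slow_baseline='cost_of_time'`` derives
    them from free-time solves with ``G_slow`` instead, which is fragile
    where that time cost saturates.  Weighted adaptation combines the two
    baselines convexly with weight ``alpha`` on the fast partner;
    interactive adaptation solves the full stochastic plan with the
    per-family sigma schedule.  Failed solves are flagged rather than
    dropped.
    """
    from .solo_oc import solve_free_time_oc  # local to allow injection
    from .synthetic import VISCOUS_INFLATION
    solve = solo_solver or solve_free_time_oc
    effort = effort or EffortCostParams()
    if slow_baseline not in ("law", "cost_of_time"):
        raise ValueError("slow_baseline must be 'law' or 'cost_of_time'")
    if slow_baseline == "cost_of_time" and G_slow is None:
        raise ValueError("slow_baseline='cost_of_time' needs G_slow")
    predictions = []
    solo_durations = {}
    for nu in viscosities:
        dyn = WristDynamics(viscosity=nu)
        for k, A in enumerate(amplitudes, start=1):
            sol = solve(dyn, effort, G_fast, A)
            solo_durations[("fast", nu, k)] = sol.duration
            if slow_baseline == "cost_of_time":
                solo_durations[("slow", nu, k)] = solve(dyn, effort, G_slow, A).duration
            else:
                infl = VISCOUS_INFLATION.get(nu, 1.0)
                solo_durations[("slow", nu, k)] = float(fit_s.predict(A)) * infl
    for nu in viscosities:
        sig = params.sigma_schedule(params.load_label(nu), len(amplitudes))
        for kappa in stiffnesses:
            coupling = CouplingParams(stiffness=kappa, viscosity=nu)
            cond = _condition_label(coupling)
            mu = tuple(solo_durations[("slow", nu, k)]
                       for k in range(1, len(amplitudes) + 1))
            slow_dist = SlowPartnerDistribution(amplitudes=tuple(amplitudes),
                                                mu=mu, sigma=tuple(sig))
            ia_cfg = InteractiveAdaptationConfig(fast_cost_of_time=G_fast,
                                                 q_tau=q_tau)
            for k in range(1, len(amplitudes) + 1):
                T_f = solo_durations[("fast", nu, k)]
                T_s = solo_durations[("slow", nu, k)]
                for hyp in hypotheses:
                    if hyp == "co_activity":
                        pred = simulate_co_activity(fit_f, fit_s, coupling, k,
                                                    amplitudes=amplitudes)
                    elif hyp == "leader_fast":
                        pred = DyadPrediction(hyp, cond, k, predicted_T=T_f)
                    elif hyp == "leader_slow":
                        pred = DyadPrediction(hyp, cond, k, predicted_T=T_s)
                    elif hyp == "weighted":
                        pred = DyadPrediction(hyp, cond, k,
                                              predicted_T=alpha * T_f + (1 - alpha) * T_s,
                                              extras={"alpha": alpha})
                    elif hyp == "interactive_adaptation":
                        dyn = WristDynamics(viscosity=nu)
                        pred = solve_interactive_adaptation(
                            ia_cfg, slow_dist, coupling, dyn=dyn,
                            effort=effort, target_index=k)
                    else:
                        raise ValueError(f"unknown hypothesis {hyp!r}")
                    pred.condition = cond
                    predictions.append(pred)
    return predictions
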