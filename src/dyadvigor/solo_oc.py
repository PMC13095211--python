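"""Optimal control of single-wrist reaching and cost-of-time identification.

The solo model is a minimum-torque-change reach: state x = (q, qdot, tau),
control u = taudot, dynamics I qddot = tau - (D + nu) qdot, and running cost

    (x_e - x)' Q (x_e - x) + beta u**2,      Q = diag(w_q, 0, 0),

with w_q = 15.5 / A for a reach of amplitude A (radians).  Movement duration
is valued through a cost of time G(t), a saturating sigmoid integral

    G(t) = p1 * (1 - [1 + (t/p3)**p2] ** (-p4)),

whose derivative g = G' is identified from the Hamiltonians of fixed-time
solves: at a free-time optimum the transversality condition g(T*) = -H(T*)
holds, so solving the fixed-time problem at each observed duration T(A_k)
and fitting g through the points (T(A_k), -H_k) recovers the time cost that
rationalizes the observed amplitude-duration law.

Free final time is handled by an outer scalar search over the horizon
(coarse log-spaced grid, then bounded refinement of every grid-local
minimum).  The landscape can be multimodal when G saturates: "time is
nearly free" basins appear at long horizons within a fraction of a percent
of the global cost.  The solver returns the smallest-duration local minimum
within 1% relative cost of the global-on-grid optimum and flags
multimodality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from ._collocation import default_node_count, solve_lq_fixed_time
from . import params
from .kinematics import AmplitudeDurationFit

__all__ = [
    "WristDynamics", "EffortCostParams", "CostOfTime", "OCSolution",
    "solve_fixed_time_oc", "identify_cost_of_time", "solve_free_time_oc",
    "predict_loaded_durations",
]


@dataclass(frozen=True)
class WristDynamics:
    """Rigid-body parameters of the wrist + exoskeleton."""

    inertia: float = params.WRIST_INERTIA      # Nm s^2
    damping: float = params.WRIST_DAMPING      # Nm s
    viscosity: float = 0.0                     # Nm s/rad

    def __post_init__(self):
        if self.inertia <= 0:
            raise ValueError("inertia must be positive")
        if self.damping < 0 or self.viscosity < 0:
            raise ValueError("damping and viscosity must be nonnegative")

    def state_matrix(self) -> np.ndarray:
        I, Dv = self.inertia, self.damping + self.viscosity
        return np.array([[0.0, 1.0, 0.0],
                         [0.0, -Dv / I, 1.0 / I],
                         [0.0, 0.0, 0.0]])

    INPUT_VECTOR = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class EffortCostParams:
    """Weights of the minimum-torque-change effort cost."""

    position_weight_scale: float = params.POSITION_WEIGHT_SCALE
    torque_change_weight: float = params.TORQUE_CHANGE_WEIGHT  # beta

    def q_weight(self, amplitude: float) -> float:
        if amplitude <= 0:
            raise ValueError("amplitude must be positive")
        return self.position_weight_scale / amplitude


@dataclass(frozen=True)
class CostOfTime:
    """Sigmoid-integral time cost G(t; p1..p4) and its derivative."""

    p1: float
    p2: float
    p3: float
    p4: float

    def __post_init__(self):
        if self.p3 <= 0:
            raise ValueError("p3 must be positive")

    def value(self, t):
        t = np.asarray(t, float)
        r = np.log1p((t / self.p3) ** self.p2)
        return -self.p1 * np.expm1(-self.p4 * r)

    def rate(self, t):
        """g(t) = dG/dt, numerically stable for degenerate (p1, p4)."""
        t = np.asarray(t, float)
        with np.errstate(divide="ignore"):
            z = (t / self.p3) ** self.p2
            logf = (-self.p4 - 1.0) * np.log1p(z)
        return (self.p1 * self.p4 * (self.p2 / self.p3)
                * (t / self.p3) ** (self.p2 - 1.0) * np.exp(logf))

    def scaled(self, factor: float) -> "CostOfTime":
        """Scale the overall magnitude of the time cost (p1 -> factor p1)."""
        return CostOfTime(self.p1 * factor, self.p2, self.p3, self.p4)

    def as_tuple(self):
        return (self.p1, self.p2, self.p3, self.p4)


@dataclass
class OCSolution:
    """One trajectory-optimization solve of the wrist reach."""

    t: np.ndarray
    q: np.ndarray
    qdot: np.ndarray
    tau: np.ndarray
    u: np.ndarray
    effort_cost: float
    hamiltonian: np.ndarray
    duration: float
    converged: bool
    flags: dict = field(default_factory=dict)

    @property
    def hamiltonian_final(self) -> float:
        """Constant Hamiltonian of the autonomous problem (interior mean)."""
        return float(np.mean(self.hamiltonian))

    def mechanical_work(self) -> float:
        """Net work of the wrist torque, int tau qdot dt (>= 0 rest-to-rest)."""
        return float(np.trapezoid(self.tau * self.qdot, self.t))


def solve_fixed_time_oc(
    dyn: WristDynamics,
    cost: EffortCostParams,
    amplitude: float,
    T: float,
    q0: float = 0.0,
    n_nodes: int | None = None,
) -> OCSolution:
    """Minimum-torque-change reach of given amplitude over a fixed horizon.

    Boundary states are fully pinned: (q0, 0, 0) -> (q0 + A, 0, 0); the
    steady torque holding either posture is zero since only velocity is
    damped.  Raises for horizons outside [0.01, 10] s or negative amplitude.
    """
    if not 0.01 <= T <= 10.0:
        raise ValueError(f"horizon {T} outside [0.01, 10] s")
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    q_e = q0 + amplitude
    if amplitude == 0.0:
        n = n_nodes or default_node_count(T)
        t = np.linspace(0, T, n + 1)
        zeros = np.zeros(n + 1)
        return OCSolution(t=t, q=np.full(n + 1, q0), qdot=zeros, tau=zeros,
                          u=zeros, effort_cost=0.0, hamiltonian=np.zeros(max(n - 3, 1)),
                          duration=T, converged=True)
    w_q = cost.q_weight(amplitude)
    res = solve_lq_fixed_time(
        T=T,
        A_c=dyn.state_matrix(),
        b_c=WristDynamics.INPUT_VECTOR,
        x0=np.array([q0, 0.0, 0.0]),
        xT=np.array([q_e, 0.0, 0.0]),
        state_weight=np.array([w_q, 0.0, 0.0]),
        u_weight=cost.torque_change_weight,
        n_nodes=n_nodes,
    )
    if not res.converged:
        warnings.warn(f"fixed-time solve did not converge (A={amplitude}, T={T})")
    return OCSolution(
        t=res.t, q=res.x[:, 0], qdot=res.x[:, 1], tau=res.x[:, 2], u=res.u,
        effort_cost=res.cost, hamiltonian=res.hamiltonian, duration=T,
        converged=res.converged, flags=dict(res.notes),
    )


# ---------------------------------------------------------------------------
# free final time

def _refine_local_minima(objective, grid, values, xatol):
    """Refine every grid-local minimum (incl. boundary minima) by bounded search."""
    n = len(grid)
    cands = []
    for i in range(n):
        left = values[i - 1] if i > 0 else np.inf
        right = values[i + 1] if i < n - 1 else np.inf
        if values[i] <= left and values[i] <= right:
            lo = grid[max(i - 1, 0)]
            hi = grid[min(i + 1, n - 1)]
            if hi <= lo:
                cands.append((grid[i], values[i]))
                continue
            r = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                                options={"xatol": xatol})
            cands.append((float(r.x), float(r.fun)))
    return cands


def _outer_duration_search(objective, t_bounds, n_grid, xatol, degeneracy_rtol):
    """Two-stage outer search over the movement duration.

    A coarse log-spaced grid locates the global basin; a finer linear grid
    over the near-optimal region (everything within twice the degeneracy
    tolerance of the grid optimum) resolves shallow competing basins that the
    coarse grid can step over.  Every local minimum of the refined grid is
    polished by bounded scalar minimization; among minima within
    ``degeneracy_rtol`` relative cost of the best, the smallest duration
    wins.  Returns (T_star, candidates, multimodal).
    """
    grid = np.geomspace(t_bounds[0], t_bounds[1], n_grid)
    values = np.array([objective(T) for T in grid])
    v_star = values.min()
    near_mask = values <= v_star * (1 + 2 * degeneracy_rtol) + 1e-12
    i_lo = max(int(np.argmax(near_mask)) - 1, 0)
    i_hi = min(int(np.argmax(values == v_star)) + 1, n_grid - 1)
    fine = np.linspace(grid[i_lo], grid[i_hi], max(n_grid, 40))
    fine_vals = np.array([objective(T) for T in fine])
    cands = _refine_local_minima(objective, fine, fine_vals, xatol)
    # keep coarse-grid minima outside the fine window too (right-hand basins)
    cands += _refine_local_minima(objective, grid[i_hi:], values[i_hi:], xatol)
    best_val = min(v for _, v in cands)
    near = sorted(t for t, v in cands if v <= best_val * (1 + degeneracy_rtol) + 1e-12)
    return float(near[0]), cands, len(near) > 1


def solve_free_time_oc(
    dyn: WristDynamics,
    cost: EffortCostParams,
    G: CostOfTime,
    amplitude: float,
    q0: float = 0.0,
    t_bounds: tuple[float, float] = (0.01, 10.0),
    n_grid: int = 48,
    xatol: float = 2e-4,
    degeneracy_rtol: float = 0.01,
) -> OCSolution:
    """Optimize effort + G(T) over control and movement duration.

    Outer search: log-spaced coarse grid over ``t_bounds`` followed by
    bounded scalar refinement of every grid-local minimum; among refined
    minima within ``degeneracy_rtol`` relative cost of the best, the
    smallest duration is returned (flag ``multimodal`` set when several
    basins are near-degenerate).
    """
    def objective(T):
        sol = solve_fixed_time_oc(dyn, cost, amplitude, T, q0=q0)
        return sol.effort_cost + float(G.value(T))

    T_star, cands, multimodal = _outer_duration_search(
        objective, t_bounds, n_grid, xatol, degeneracy_rtol)
    sol = solve_fixed_time_oc(dyn, cost, amplitude, T_star, q0=q0)
    sol.flags["total_cost"] = sol.effort_cost + float(G.value(T_star))
    sol.flags["multimodal"] = multimodal
    sol.flags["candidates"] = cands
    return sol


def predict_loaded_durations(
    G: CostOfTime,
    amplitudes=params.TARGET_AMPLITUDES_RAD,
    viscosities=params.VISCOUS_LOADS,
    cost: EffortCostParams | None = None,
    inertia: float = params.WRIST_INERTIA,
    damping: float = params.WRIST_DAMPING,
    **free_time_kwargs,
):
    """Free-time durations, effort and mechanical work per (nu, amplitude).

    Returns a list of dict rows (viscosity, amplitude, duration, effort,
    work, multimodal) suitable for a DataFrame.
    """
    cost = cost or EffortCostParams()
    rows = []
    for nu in viscosities:
        dyn = WristDynamics(inertia=inertia, damping=damping, viscosity=nu)
        for A in amplitudes:
            sol = solve_free_time_oc(dyn, cost, G, A, **free_time_kwargs)
            rows.append({
                "viscosity": nu, "amplitude": A, "duration": sol.duration,
                "effort": sol.effort_cost, "work": sol.mechanical_work(),
                "multimodal": bool(sol.flags.get("multimodal", False)),
            })
    return rows


# ---------------------------------------------------------------------------
# inverse identification of the cost of time

def identify_cost_of_time(
    ad_fit: AmplitudeDurationFit,
    dyn: WristDynamics | None = None,
    cost: EffortCostParams | None = None,
    amplitudes=params.TARGET_AMPLITUDES_RAD,
    n_starts: int = 20,
    seed: int = 0,
    fix_p4: float | None = None,
    weighting: str = "linear",
    residual_warn: float = 0.5,
) -> CostOfTime:
    """Identify G(t) from an amplitude-duration law by inverse optimal control.

    For each amplitude the fixed-time problem is solved at the law's duration
    and the (constant) Hamiltonian collected; g(t; p) is then fitted by
    multi-start nonlinear least squares through the points (T_k, -H_k) and
    integrated into G.  ``weighting='relative'`` divides residuals by the
    observed magnitudes (useful when the Hamiltonians span orders of
    magnitude); the default unweighted fit reproduces published
    identifications.  ``fix_p4`` pins the saturation exponent.
    """
    dyn = dyn or WristDynamics()
    cost = cost or EffortCostParams()
    if dyn.viscosity != 0:
        raise ValueError("identification is defined for null-field dynamics")
    amplitudes = np.asarray(amplitudes, float)
    if len(amplitudes) < 2:
        raise ValueError("need at least two amplitudes")
    T_k = ad_fit.predict(amplitudes)
    neg_H = np.empty_like(T_k)
    for i, (A, T) in enumerate(zip(amplitudes, T_k)):
        sol = solve_fixed_time_oc(dyn, cost, A, T)
        neg_H[i] = -sol.hamiltonian_final
    scale = np.maximum(np.abs(neg_H), 1e-8) if weighting == "relative" else np.ones_like(neg_H)

    def residual(theta):
        p1, p2, p3 = np.exp(theta[0]), theta[1], np.exp(theta[2])
        p4 = fix_p4 if fix_p4 is not None else np.exp(theta[3])
        g = CostOfTime(p1, p2, p3, p4).rate(T_k)
        return (g - neg_H) / scale

    rng = np.random.default_rng(seed)
    best = None
    n_free = 3 if fix_p4 is not None else 4
    for _ in range(n_starts):
        th0 = np.array([
            rng.uniform(np.log(0.05), np.log(50.0)),
            rng.uniform(1.0, 14.0),
            rng.uniform(np.log(0.1), np.log(3.0)),
            rng.uniform(np.log(1e-4), np.log(10.0)),
        ])[:n_free]
        lb = np.array([np.log(1e-8), 0.1, np.log(0.01), np.log(1e-6)])[:n_free]
        ub = np.array([np.log(1e9), 40.0, np.log(20.0), np.log(10.0)])[:n_free]
        try:
            res = least_squares(residual, th0, bounds=(lb, ub), max_nfev=3000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("cost-of-time fit failed for every start")
    th = best.x
    p4 = fix_p4 if fix_p4 is not None else float(np.exp(th[3]))
    G = CostOfTime(float(np.exp(th[0])), float(th[1]), float(np.exp(th[2])), p4)
    rel_res = float(np.linalg.norm(G.rate(T_k) - neg_H) / max(np.linalg.norm(neg_H), 1e-12))
    if rel_res > residual_warn:
        warnings.warn(f"cost-of-time fit residual {rel_res:.2f} exceeds {residual_warn}")
    object.__setattr__(G, "_fit_diagnostics", {
        "durations": T_k, "neg_hamiltonians": neg_H,
        "relative_residual": rel_res,
    })
    return G
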