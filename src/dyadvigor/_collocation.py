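"""Sparse direct-collocation core for linear-quadratic trajectory optimization.

Every trajectory-optimization subproblem in this package -- the
minimum-torque-change reach, the cost-of-time identification solves, and the
coupled interactive-adaptation plan -- has linear (possibly time-varying
forced) dynamics and a convex quadratic running cost.  Trapezoidal direct
transcription therefore yields an equality-constrained quadratic program
whose KKT system is a sparse symmetric linear system that can be solved
exactly in one factorization.  This module implements that transcription for
a single-input system with an arbitrary number of states, and recovers the
costates (and with them the Hamiltonian) from the KKT multipliers.

Sign conventions.  With running cost L and dynamics f, the Hamiltonian is
H = L + p'f where p is the costate of the minimization problem; along an
optimal trajectory of an autonomous problem H is constant and equals the
sensitivity dE*/dT of the optimal cost to the horizon.  The discrete costate
at interior node i is recovered as -(lam[i-1] + lam[i]) / 2 from the defect
multipliers lam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["LQCollocationResult", "solve_lq_fixed_time", "default_node_count"]


@dataclass
class LQCollocationResult:
    """Solution of one fixed-horizon linear-quadratic collocation solve."""

    t: np.ndarray                 # node times, shape (N+1,)
    x: np.ndarray                 # states, shape (N+1, n_x)
    u: np.ndarray                 # control, shape (N+1,)
    cost: float                   # optimal running cost (integral only)
    costate: np.ndarray           # recovered costates, shape (N+1, n_x)
    hamiltonian: np.ndarray       # pointwise H at interior nodes
    converged: bool = True
    notes: dict = field(default_factory=dict)

    @property
    def hamiltonian_mean(self) -> float:
        return float(np.mean(self.hamiltonian))


def default_node_count(T: float, per_second: int = 300,
                       lo: int = 120, hi: int = 1500) -> int:
    """Node count scaling with the horizon so the time step stays ~3 ms."""
    return int(np.clip(int(round(T * per_second)), lo, hi))


def solve_lq_fixed_time(
    T: float,
    A_c: np.ndarray,
    b_c: np.ndarray,
    x0: np.ndarray,
    xT: np.ndarray,
    state_weight: np.ndarray,
    u_weight: float,
    state_ref: np.ndarray | None = None,
    forcing: np.ndarray | None = None,
    n_nodes: int | None = None,
) -> LQCollocationResult:
    """Minimize ``int (x - r)' W (x - r) + w_u u^2 dt`` subject to
    ``xdot = A_c x + b_c u + c(t)`` and pinned boundary states.

    Parameters
    ----------
    T:
        Horizon in seconds (must be positive).
    A_c, b_c:
        Continuous-time dynamics matrix (n_x, n_x) and input vector (n_x,).
    x0, xT:
        Boundary states, fully pinned at both ends.
    state_weight:
        Diagonal running-cost weights; shape (n_x,) for constant weights or
        (N+1, n_x) for time-varying ones.
    u_weight:
        Strictly positive weight on the squared control.
    state_ref:
        Reference for the state error; defaults to ``xT`` at every node.
        Shape (n_x,) or (N+1, n_x).
    forcing:
        Known additive forcing c(t) sampled at the nodes, shape (N+1, n_x).
    n_nodes:
        Number of trapezoidal intervals N; defaults to `default_node_count`.
    """
    if not np.isfinite(T) or T <= 0:
        raise ValueError(f"horizon must be positive, got {T}")
    if u_weight <= 0:
        raise ValueError("control weight must be strictly positive")
    n_x = A_c.shape[0]
    N = int(n_nodes) if n_nodes is not None else default_node_count(T)
    if N < 2:
        raise ValueError("need at least 2 collocation intervals")
    n = N + 1
    h = T / N
    t = np.linspace(0.0, T, n)

    W = np.asarray(state_weight, float)
    if W.ndim == 1:
        W = np.broadcast_to(W, (n, n_x))
    ref = np.asarray(xT, float) if state_ref is None else np.asarray(state_ref, float)
    if ref.ndim == 1:
        ref = np.broadcast_to(ref, (n, n_x))
    c_t = np.zeros((n, n_x)) if forcing is None else np.asarray(forcing, float)

    # trapezoid quadrature weights
    w = np.full(n, h)
    w[0] = w[-1] = h / 2

    nz = (n_x + 1) * n  # [x_0, u_0, x_1, u_1, ...]
    stride = n_x + 1

    Hdiag = np.zeros(nz)
    g = np.zeros(nz)
    const = 0.0
    for j in range(n_x):
        idx = np.arange(n) * stride + j
        Hdiag[idx] = 2.0 * w * W[:, j]
        g[idx] = -2.0 * w * W[:, j] * ref[:, j]
        const += float(np.sum(w * W[:, j] * ref[:, j] ** 2))
    Hdiag[np.arange(n) * stride + n_x] = 2.0 * w * u_weight
    H = sp.diags(Hdiag, format="csr")

    # defect constraints x_{i+1} - x_i - h/2 (f_i + f_{i+1}) = 0
    A1 = -(np.eye(n_x) + (h / 2) * A_c)   # block on x_i
    A2 = np.eye(n_x) - (h / 2) * A_c      # block on x_{i+1}
    rows, cols, vals = [], [], []
    for i in range(N):
        r0 = n_x * i
        s, s2 = stride * i, stride * (i + 1)
        for a in range(n_x):
            for bcol in range(n_x):
                rows.append(r0 + a); cols.append(s + bcol); vals.append(A1[a, bcol])
                rows.append(r0 + a); cols.append(s2 + bcol); vals.append(A2[a, bcol])
            rows.append(r0 + a); cols.append(s + n_x); vals.append(-(h / 2) * b_c[a])
            rows.append(r0 + a); cols.append(s2 + n_x); vals.append(-(h / 2) * b_c[a])
    b_eq = np.zeros(n_x * N + 2 * n_x)
    for i in range(N):
        b_eq[n_x * i:n_x * i + n_x] = (h / 2) * (c_t[i] + c_t[i + 1])
    # boundary rows
    r0 = n_x * N
    for a in range(n_x):
        rows.append(r0 + a); cols.append(a); vals.append(1.0)
        rows.append(r0 + n_x + a); cols.append(stride * N + a); vals.append(1.0)
    b_eq[r0:r0 + n_x] = np.asarray(x0, float)
    b_eq[r0 + n_x:] = np.asarray(xT, float)
    M = sp.coo_matrix((vals, (rows, cols)), shape=(n_x * N + 2 * n_x, nz)).tocsr()

    KKT = sp.bmat([[H, M.T], [M, None]], format="csc")
    rhs = np.concatenate([-g, b_eq])
    try:
        sol = spla.splu(KKT).solve(rhs)
        converged = bool(np.all(np.isfinite(sol)))
    except RuntimeError:
        sol = np.full(KKT.shape[0], np.nan)
        converged = False

    z = sol[:nz]
    lam = sol[nz:nz + n_x * N].reshape(N, n_x)
    X = z.reshape(n, stride)
    x_opt = X[:, :n_x]
    u_opt = X[:, n_x]
    cost = float(0.5 * z @ (H @ z) + g @ z + const)

    costate = np.zeros((n, n_x))
    if N >= 2:
        costate[1:N] = -(lam[:-1] + lam[1:]) / 2
    costate[0] = -lam[0]
    costate[N] = -lam[N - 1]

    interior = slice(2, n - 2) if n > 6 else slice(0, n)
    xi = x_opt[interior]
    ui = u_opt[interior]
    L = np.einsum("ij,ij->i", (xi - ref[interior]) ** 2, W[interior]) + u_weight * ui ** 2
    f = xi @ A_c.T + np.outer(ui, b_c) + c_t[interior]
    ham = L + np.einsum("ij,ij->i", costate[interior], f)

    return LQCollocationResult(
        t=t, x=x_opt, u=u_opt, cost=cost, costate=costate,
        hamiltonian=ham, converged=converged,
        notes={"n_nodes": N, "h": h},
    )
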