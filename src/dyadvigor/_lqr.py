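"""Finite-horizon time-varying LQR tracking for the coupled wrist dynamics.

State (q_f, qdot_f, q_s, qdot_s), controls (tau_f, tau_s):

    I qddot_f = tau_f - (D + nu) qdot_f - kappa (q_f - q_s)
    I qddot_s = tau_s - (D + nu) qdot_s - kappa (q_s - q_f)

The tracking controller minimizes sum (x - r)' Q (x - r) + u' R u over the
horizon via a backward Riccati recursion with an affine feedforward term,
discretized with explicit Euler at the simulation step.
"""

from __future__ import annotations

import numpy as np

from . import params

__all__ = ["coupled_matrices", "tracking_lqr_gains", "simulate_tracking"]


def coupled_matrices(kappa: float, nu: float,
                     inertia: float = params.WRIST_INERTIA,
                     damping: float = params.WRIST_DAMPING):
    I, Dv = inertia, damping + nu
    A = np.array([
        [0.0, 1.0, 0.0, 0.0],
        [-kappa / I, -Dv / I, kappa / I, 0.0],
        [0.0, 0.0, 0.0, 1.0],
        [kappa / I, 0.0, -kappa / I, -Dv / I],
    ])
    B = np.array([[0.0, 0.0], [1.0 / I, 0.0], [0.0, 0.0], [0.0, 1.0 / I]])
    return A, B


def tracking_lqr_gains(A, B, Q, R, ref, dt):
    """Backward pass: feedback gains K_k and feedforward terms for each step."""
    n = ref.shape[0]
    Ad = np.eye(A.shape[0]) + A * dt
    Bd = B * dt
    Qd, Rd = Q * dt, R * dt
    S = Q * dt
    b = S @ ref[-1]
    Ks = np.zeros((n - 1, B.shape[1], A.shape[0]))
    ffs = np.zeros((n - 1, B.shape[1]))
    for k in range(n - 2, -1, -1):
        M = Rd + Bd.T @ S @ Bd
        Minv = np.linalg.inv(M)
        K = Minv @ Bd.T @ S @ Ad
        Ks[k] = K
        ffs[k] = Minv @ Bd.T @ b
        S = Qd + Ad.T @ S @ Ad - Ad.T @ S @ Bd @ K
        b = Qd @ ref[k] + (Ad - Bd @ K).T @ b
        if not np.all(np.isfinite(S)):
            raise FloatingPointError("Riccati backward pass diverged")
    return Ks, ffs, Ad, Bd


def simulate_tracking(A, B, Q, R, ref, dt, x0=None):
    """Closed-loop trajectory tracking the reference; returns states (n, 4)."""
    Ks, ffs, Ad, Bd = tracking_lqr_gains(A, B, Q, R, ref, dt)
    n = ref.shape[0]
    x = ref[0].copy() if x0 is None else np.asarray(x0, float).copy()
    traj = np.zeros((n, A.shape[0]))
    traj[0] = x
    for k in range(n - 1):
        u = -Ks[k] @ x + ffs[k]
        x = Ad @ x + Bd @ u
        traj[k + 1] = x
    return traj
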