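"""Reference parameters of the coupled wrist-reaching task and its models.

Published group-level quantities used across the package: target set, load
and coupling levels, group amplitude-duration laws, identified cost-of-time
parameter sets, and the interactive-adaptation weights.  Angles are radians
everywhere inside the package; degrees appear only at I/O boundaries.
"""

from __future__ import annotations

import numpy as np

#: Target amplitudes of the reaching task.
TARGET_AMPLITUDES_DEG = (18.0, 36.0, 54.0, 72.0, 90.0)
TARGET_AMPLITUDES_RAD = tuple(np.deg2rad(TARGET_AMPLITUDES_DEG))

#: Viscous load levels nu [Nm s/rad]: null field, low (VL), high (VH).
VISCOUS_LOADS = (0.0, 0.075, 0.15)

#: Elastic coupling stiffness kappa [Nm/rad]: low (KL) and high (KH).
COUPLING_STIFFNESS = {"KL": 0.5, "KH": 1.6}

#: Wrist + exoskeleton rigid-body parameters.
WRIST_INERTIA = 9.2e-3   # Nm s^2
WRIST_DAMPING = 0.03     # Nm s

#: Effort-cost weights of the minimum-torque-change model:
#: position-error weight 15.5 / A (A in rad) and torque-change weight.
POSITION_WEIGHT_SCALE = 15.5
TORQUE_CHANGE_WEIGHT = 0.95

#: Group amplitude-duration laws T(A) = slope * A + intercept (A in rad).
AD_LAW_AVERAGE = (0.314, 0.298)
AD_LAW_FAST = (0.235, 0.285)
AD_LAW_SLOW = (0.35, 0.323)

#: Identified cost-of-time sigmoid parameters (p1, p2, p3, p4) per group.
COST_OF_TIME_AVERAGE = (1.5713, 6.9723, 0.4497, 1.0)
COST_OF_TIME_FAST = (3.9615, 5.8958, 0.4459, 1.0)
COST_OF_TIME_SLOW = (1.0184e7, 11.2958, 1.9980, 1.4447e-5)

#: Interactive-adaptation weight on interaction-torque variation.
Q_TAU = 3.0

#: Slow-partner timing-uncertainty ranges (sigma_k, seconds), spread linearly
#: from the smallest to the largest target within each load family.
SIGMA_RANGES = {
    "none": (0.15, 0.25),   # KL, KH (no viscous load)
    "VL": (0.2, 0.3),       # KLVL, KHVL
    "VH": (0.32, 0.4),      # KLVH, KHVH
}

#: Encoder resolution: 6400 counts per turn.
ENCODER_QUANTUM = 2.0 * np.pi / 6400.0

#: Recording rate of the wrist encoders.
SAMPLE_RATE_HZ = 300.0

CONDITION_FAMILIES = {
    "KL": ("KL", 0.5, 0.0), "KH": ("KH", 1.6, 0.0),
    "KLVL": ("KL", 0.5, 0.075), "KHVL": ("KH", 1.6, 0.075),
    "KLVH": ("KL", 0.5, 0.15), "KHVH": ("KH", 1.6, 0.15),
}


def sigma_schedule(load_label: str, n_targets: int = 5) -> np.ndarray:
    """Timing-uncertainty sigma_k per target, increasing with amplitude."""
    lo, hi = SIGMA_RANGES[load_label]
    return np.linspace(lo, hi, n_targets)


def load_label(nu: float) -> str:
    if np.isclose(nu, 0.0):
        return "none"
    if np.isclose(nu, 0.075):
        return "VL"
    if np.isclose(nu, 0.15):
        return "VH"
    raise ValueError(f"unknown viscous load {nu}")
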