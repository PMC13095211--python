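"""Synthetic solo and dyadic wrist-reaching sessions.

Generates per-trial angle time series with the statistical structure the
downstream analysis assumes: affine per-subject amplitude-duration laws with
log-normal trial-to-trial jitter, minimum-jerk kinematics, reaction-time
jitter, uniform inter-trial onset jitter (2 +/- 0.15 s), viscous-load
slowing, elastic coupling with the interaction torque recorded pointwise,
Gaussian sensor noise and optional encoder quantization (6400 counts/turn).
Every stream of randomness descends from the session seed, so identical
configurations reproduce byte-identical sessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import params
from ._lqr import coupled_matrices, tracking_lqr_gains

__all__ = [
    "SubjectProfile", "SessionConfig", "TrialTimeSeries",
    "sample_movement_duration", "generate_minimum_jerk_trial",
    "generate_solo_session", "generate_dyad_session",
    "write_session", "read_session",
]

#: Default per-load duration inflation applied by the generator, consistent
#: with the forward optimal-control predictions on their stable branch
#: (movements slow under viscous load, more under the high load).
VISCOUS_INFLATION = {0.0: 1.0, 0.075: 1.15, 0.15: 1.30}

COORDINATION_MODES = ("co_activity", "leader_fast", "leader_slow", "weighted", "common_plan")


@dataclass(frozen=True)
class SubjectProfile:
    """Idiosyncratic movement-timing parameters of one participant."""

    subject_id: str
    ad_slope: float               # s/rad
    ad_intercept: float           # s
    duration_cv: float = 0.05     # trial-to-trial CV of duration
    reaction_mean: float = 0.225  # s
    reaction_sd: float = 0.04     # s
    noise_sd: float = 0.002       # rad, sensor noise on angle

    def __post_init__(self):
        if self.ad_slope <= 0 or self.ad_intercept <= 0:
            raise ValueError("amplitude-duration law must have positive slope and intercept")
        if not 0.0 <= self.duration_cv <= 0.5:
            raise ValueError("duration_cv must lie in [0, 0.5]")
        if self.reaction_mean <= 0:
            raise ValueError("reaction_mean must be positive")


@dataclass(frozen=True)
class SessionConfig:
    """Protocol parameters of one recording session."""

    targets_rad: tuple = params.TARGET_AMPLITUDES_RAD
    trials_per_target_per_direction: int = 10
    viscosity: float = 0.0                 # Nm s/rad
    stiffness: float = 0.0                 # Nm/rad (0 for solo)
    hold_mean: float = 2.0                 # s
    hold_jitter: float = 0.15              # s, uniform half-width
    sample_rate: float = params.SAMPLE_RATE_HZ
    post_hold: float = 0.5                 # s of hold recorded after arrival
    quantize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.trials_per_target_per_direction < 1:
            raise ValueError("need at least one trial per target and direction")
        if min(self.targets_rad) <= 0:
            raise ValueError("target amplitudes must be positive")


@dataclass
class TrialTimeSeries:
    """Sampled kinematics (and coupling torque) of one trial."""

    t: np.ndarray
    q: np.ndarray                        # primary channel, rad
    target_onset: float
    target_amplitude: float              # signed, rad
    direction: str
    condition: str
    sample_rate: float
    target_index: int | None = None
    q_partner: np.ndarray | None = None  # second channel for dyad trials
    tau_interaction: np.ndarray | None = None
    entity_id: str | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        dt = np.diff(self.t)
        if not np.all(dt > 0) or not np.allclose(dt, dt[0], rtol=1e-9):
            raise ValueError("time grid must be strictly increasing and uniform")


def sample_movement_duration(profile: SubjectProfile, amplitude: float,
                             rng: np.random.Generator) -> float:
    """Draw one movement duration from the subject's affine law.

    The law value is multiplied by a log-normal factor with unit mean and
    coefficient of variation ``profile.duration_cv`` (positive, right-skewed,
    as movement durations are).
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    base = profile.ad_slope * amplitude + profile.ad_intercept
    cv = profile.duration_cv
    if cv == 0:
        return base
    sigma2 = np.log1p(cv ** 2)
    m = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2))
    return float(base * m)


def _minimum_jerk(tau_rel):
    """Unit minimum-jerk position and its d/dt (per unit duration)."""
    z = np.clip(tau_rel, 0.0, 1.0)
    pos = z ** 3 * (10.0 - 15.0 * z + 6.0 * z ** 2)
    vel = 30.0 * z ** 2 * (1.0 - z) ** 2
    return pos, vel


def generate_minimum_jerk_trial(
    q0: float,
    amplitude: float,
    duration: float,
    reaction_time: float,
    cfg: SessionConfig,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
    hold_before: float | None = None,
    condition: str = "NF1",
    target_index: int | None = None,
    entity_id: str | None = None,
) -> TrialTimeSeries:
    """One solo trial: hold, reaction, minimum-jerk movement, hold.

    The noiseless trace is exactly the quintic minimum-jerk polynomial
    between movement onset and arrival and constant outside it.  Gaussian
    angle noise and (optionally) encoder quantization are applied last.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    fs = cfg.sample_rate
    if duration * fs < 20:
        raise ValueError(
            f"grid too coarse: {duration * fs:.1f} samples in the movement (need >= 20)")
    hold = (cfg.hold_mean + rng.uniform(-cfg.hold_jitter, cfg.hold_jitter)
            if hold_before is None else hold_before)
    total = hold + reaction_time + duration + cfg.post_hold
    n = int(np.ceil(total * fs)) + 1
    t = np.arange(n) / fs
    move_start = hold + reaction_time
    pos, _ = _minimum_jerk((t - move_start) / duration)
    q = q0 + amplitude * pos
    if noise_sd > 0:
        q = q + rng.normal(0.0, noise_sd, size=n)
    if cfg.quantize:
        q = np.round(q / params.ENCODER_QUANTUM) * params.ENCODER_QUANTUM
    return TrialTimeSeries(
        t=t, q=q, target_onset=hold, target_amplitude=amplitude,
        direction="extension" if amplitude >= 0 else "flexion",
        condition=condition, sample_rate=fs, target_index=target_index,
        entity_id=entity_id,
    )


def _trial_order(n_targets: int, reps: int, rng: np.random.Generator):
    """Pseudo-random (target, direction) sequence: out/back pairs shuffled."""
    pairs = [(k, 1) for k in range(n_targets) for _ in range(reps)]
    rng.shuffle(pairs)
    order = []
    for k, _ in pairs:
        order.append((k, "extension"))
        order.append((k, "flexion"))
    return order


def generate_solo_session(profile: SubjectProfile, cfg: SessionConfig,
                          rng: np.random.Generator | None = None):
    """A block of solo trials: out and back movements to every target.

    With the default configuration this yields 100 trials (10 extensions and
    10 flexions per each of the five targets) in a seed-fixed pseudo-random
    order.  Under viscous load the sampled durations are inflated by the
    per-load factor so loaded blocks are slower by construction.
    """
    if cfg.stiffness != 0:
        raise ValueError("solo sessions require zero coupling stiffness")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    inflation = VISCOUS_INFLATION.get(cfg.viscosity)
    if inflation is None:
        raise ValueError(f"no duration inflation configured for nu={cfg.viscosity}")
    condition = {0.0: "NF1", 0.075: "VL", 0.15: "VH"}.get(cfg.viscosity, "solo")
    trials = []
    for k, direction in _trial_order(len(cfg.targets_rad),
                                     cfg.trials_per_target_per_direction, rng):
        A = cfg.targets_rad[k]
        dur = sample_movement_duration(profile, A, rng) * inflation
        rt = max(rng.normal(profile.reaction_mean, profile.reaction_sd), 0.05)
        signed = A if direction == "extension" else -A
        q0 = 0.0 if direction == "extension" else A
        trials.append(generate_minimum_jerk_trial(
            q0, signed, dur, rt, cfg, rng, noise_sd=profile.noise_sd,
            condition=condition, target_index=k + 1, entity_id=profile.subject_id))
    return trials


# ---------------------------------------------------------------------------
# dyadic sessions

def _reference_durations(profile_f, profile_s, amplitude, coordination, rng,
                         shared_duration=None):
    d_f = sample_movement_duration(profile_f, amplitude, rng)
    d_s = sample_movement_duration(profile_s, amplitude, rng)
    if coordination == "co_activity":
        return d_f, d_s
    if coordination == "leader_fast":
        return d_f, d_f
    if coordination == "leader_slow":
        return d_s, d_s
    if coordination == "weighted":
        d = 0.5 * (d_f + d_s)
        return d, d
    if coordination == "common_plan":
        d = shared_duration if shared_duration is not None else 0.5 * (d_f + d_s)
        return d, d
    raise ValueError(f"unknown coordination mode {coordination!r}")


def generate_dyad_session(
    profile_f: SubjectProfile,
    profile_s: SubjectProfile,
    cfg: SessionConfig,
    coordination: str = "common_plan",
    rng: np.random.Generator | None = None,
    shared_duration: float | None = None,
    lqr_q: tuple = (100.0, 0.1, 100.0, 0.1),
):
    """Coupled trials: per-partner references tracked through the coupled
    dynamics by a finite-horizon LQR, integrated with explicit Euler at the
    sample rate, with the interaction torque kappa (q_f - q_s) recorded.

    The reference plans follow the named coordination hypothesis;
    ``common_plan`` uses the caller-supplied shared duration (or the
    partners' mean).  Trials whose integration exceeds 10 rad are flagged.
    """
    if cfg.stiffness <= 0:
        raise ValueError("dyad sessions require positive coupling stiffness")
    if coordination not in COORDINATION_MODES:
        raise ValueError(f"coordination must be one of {COORDINATION_MODES}")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    kappa = cfg.stiffness
    inflation = VISCOUS_INFLATION.get(cfg.viscosity, 1.0)
    fam = {0.0: "", 0.075: "VL", 0.15: "VH"}.get(cfg.viscosity, "")
    condition = ("KL" if np.isclose(kappa, 0.5) else "KH") + fam
    fs = cfg.sample_rate
    dt = 1.0 / fs
    A_sys, B_sys = coupled_matrices(kappa, cfg.viscosity)
    Q = np.diag(lqr_q)
    R = np.eye(2)
    dyad_id = f"{profile_f.subject_id}+{profile_s.subject_id}"

    trials = []
    for k, direction in _trial_order(len(cfg.targets_rad),
                                     cfg.trials_per_target_per_direction, rng):
        A_amp = cfg.targets_rad[k]
        d_f, d_s = _reference_durations(profile_f, profile_s, A_amp, coordination,
                                        rng, shared_duration)
        d_f *= inflation
        d_s *= inflation
        rt = max(rng.normal(0.5 * (profile_f.reaction_mean + profile_s.reaction_mean),
                            0.5 * (profile_f.reaction_sd + profile_s.reaction_sd)), 0.05)
        hold = cfg.hold_mean + rng.uniform(-cfg.hold_jitter, cfg.hold_jitter)
        signed = A_amp if direction == "extension" else -A_amp
        q0 = 0.0 if direction == "extension" else A_amp
        total = hold + rt + max(d_f, d_s) + cfg.post_hold
        n = int(np.ceil(total * fs)) + 1
        t = np.arange(n) / fs
        move_start = hold + rt
        pos_f, vel_f = _minimum_jerk((t - move_start) / d_f)
        pos_s, vel_s = _minimum_jerk((t - move_start) / d_s)
        ref = np.stack([
            q0 + signed * pos_f, signed * vel_f / d_f * (((t - move_start) >= 0) & ((t - move_start) < d_f)),
            q0 + signed * pos_s, signed * vel_s / d_s * (((t - move_start) >= 0) & ((t - move_start) < d_s)),
        ], axis=1)
        try:
            Ks, ffs, Ad, Bd = tracking_lqr_gains(A_sys, B_sys, Q, R, ref, dt)
            unstable = False
        except FloatingPointError:
            Ks = ffs = None
            unstable = True
        x = np.array([q0, 0.0, q0, 0.0])
        traj = np.zeros((n, 4))
        traj[0] = x
        if not unstable:
            for i in range(n - 1):
                u = -Ks[i] @ x + ffs[i]
                x = Ad @ x + Bd @ u
                traj[i + 1] = x
                if np.abs(x[[0, 2]]).max() > 10.0:
                    unstable = True
                    traj[i + 1:] = x
                    break
        q_f = traj[:, 0] + rng.normal(0.0, profile_f.noise_sd, n)
        q_s = traj[:, 2] + rng.normal(0.0, profile_s.noise_sd, n)
        if cfg.quantize:
            q_f = np.round(q_f / params.ENCODER_QUANTUM) * params.ENCODER_QUANTUM
            q_s = np.round(q_s / params.ENCODER_QUANTUM) * params.ENCODER_QUANTUM
        trial = TrialTimeSeries(
            t=t, q=q_f, q_partner=q_s, tau_interaction=kappa * (q_f - q_s),
            target_onset=hold, target_amplitude=signed, direction=direction,
            condition=condition, sample_rate=fs, target_index=k + 1,
            entity_id=dyad_id, flags={"unstable": unstable},
        )
        trials.append(trial)
    return trials


# ---------------------------------------------------------------------------
# on-disk format: one CSV per trial plus a session manifest

def write_session(trials, out_dir, manifest_extra=None):
    """One CSV per trial (t, q_f[, q_s, tau_i]) and a manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = []
    for i, tr in enumerate(trials):
        cols = {"t": tr.t, "q_f": tr.q}
        if tr.q_partner is not None:
            cols["q_s"] = tr.q_partner
            cols["tau_i"] = tr.tau_interaction
        name = f"trial_{i:04d}.csv"
        pd.DataFrame(cols).to_csv(out / name, index=False, float_format="%.9g")
        index.append({
            "file": name, "entity_id": tr.entity_id, "condition": tr.condition,
            "target_index": tr.target_index, "target_amplitude": tr.target_amplitude,
            "direction": tr.direction, "target_onset": tr.target_onset,
            "sample_rate": tr.sample_rate, "flags": tr.flags,
        })
    manifest = {"trials": index}
    if manifest_extra:
        manifest.update(manifest_extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out / "manifest.json"


def read_session(session_dir):
    """Load the trials written by `write_session`."""
    d = Path(session_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    trials = []
    for rec in manifest["trials"]:
        df = pd.read_csv(d / rec["file"])
        trials.append(TrialTimeSeries(
            t=df["t"].to_numpy(), q=df["q_f"].to_numpy(),
            q_partner=df["q_s"].to_numpy() if "q_s" in df else None,
            tau_interaction=df["tau_i"].to_numpy() if "tau_i" in df else None,
            target_onset=rec["target_onset"],
            target_amplitude=rec["target_amplitude"],
            direction=rec["direction"], condition=rec["condition"],
            sample_rate=rec["sample_rate"], target_index=rec["target_index"],
            entity_id=rec["entity_id"], flags=rec.get("flags", {}),
        ))
    return trials, manifest
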