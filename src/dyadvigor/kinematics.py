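"""Kinematic preprocessing: filtering, segmentation, and duration analysis.

Turns raw wrist-angle time series into segmented movements with durations,
reaction times, interaction-torque summaries, amplitude-duration fits and
spectral smoothness scores.  The processing chain mirrors standard practice
for encoder kinematics: zero-phase low-pass filtering (5th-order Butterworth,
5 Hz cutoff, forward-backward), numerical differentiation, coarse windows
from target timing refined by a 5%-of-peak-speed threshold, and per-target
averaging before affine regression of duration on amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "MovementSegment", "AmplitudeDurationFit",
    "filter_position", "differentiate", "segment_movements", "reaction_time",
    "fit_amplitude_duration", "fit_amplitude_duration_group",
    "mean_abs_interaction_torque", "spectral_smoothness",
    "segments_table",
]

FILTER_ORDER = 5
FILTER_CUTOFF_HZ = 5.0
SPEED_THRESHOLD_FRACTION = 0.05
REACTION_SPEED_THRESHOLD = 0.01  # rad/s
PEAK_SPEED_FLOOR = 0.02          # rad/s, windows below this carry no movement
SEGMENT_WINDOW_S = 1.9           # respects the 2 s target display


@dataclass
class MovementSegment:
    """One segmented point-to-point movement."""

    t_start: float
    t_end: float
    amplitude: float          # signed, rad
    peak_velocity: float      # rad/s (speed at peak)
    direction: str            # "flexion" | "extension"
    target_index: int | None = None
    mean_abs_tau_i: float | None = None
    smoothness: float | None = None

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise ValueError("segment must have positive duration")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class AmplitudeDurationFit:
    """Affine law T(A) = slope * A + intercept fitted on per-target means."""

    slope: float              # s/rad
    intercept: float          # s
    r_squared: float
    n_points: int
    degenerate: bool = False

    def predict(self, amplitude):
        return self.slope * np.asarray(amplitude, float) + self.intercept


def filter_position(q: np.ndarray, sample_rate: float) -> np.ndarray:
    """Zero-phase 5th-order Butterworth low-pass at 5 Hz."""
    q = np.asarray(q, float)
    if sample_rate <= 10.0:
        raise ValueError("sample rate must exceed 10 Hz for a 5 Hz cutoff")
    sos = signal.butter(FILTER_ORDER, FILTER_CUTOFF_HZ, fs=sample_rate, output="sos")
    # forward-backward filtering needs padding several times the filter order
    min_len = 3 * (2 * FILTER_ORDER + 1)
    if q.size <= min_len:
        raise ValueError(
            f"series of {q.size} samples too short for zero-phase filtering "
            f"(need > {min_len})")
    # pad by a few time constants of the 5 Hz response, not just the order,
    # so edge transients decay inside the padding
    padlen = min(q.size - 1, int(3 * sample_rate / FILTER_CUTOFF_HZ))
    return signal.sosfiltfilt(sos, q, padlen=padlen)


def differentiate(q: np.ndarray, sample_rate: float):
    """Velocity and acceleration by central differences (one-sided at ends)."""
    q = np.asarray(q, float)
    if q.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    dt = 1.0 / sample_rate
    vel = np.gradient(q, dt)
    acc = np.gradient(vel, dt)
    return vel, acc


def _threshold_regions(speed: np.ndarray, threshold: float):
    """Contiguous index runs where speed >= threshold."""
    above = speed >= threshold
    if not above.any():
        return []
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(speed) - 1)
    return list(zip(starts, ends))


def segment_movements(trial, channel: str = "q", prefiltered: bool = False):
    """Segment the movements of one trial by the 5%-of-peak-speed rule.

    A coarse window [target_onset, target_onset + 1.9 s] is taken from the
    target timing; within it, every contiguous run of speed above 5% of the
    window peak becomes a candidate segment (so a full stop between
    submovements splits them).  Windows whose peak speed is below a 0.02
    rad/s floor are dropped.  Flexion and extension segments are labelled by
    the sign of the displacement and pooled downstream.
    """
    q = getattr(trial, channel)
    fs = trial.sample_rate
    t = trial.t
    qf = q if prefiltered else filter_position(q, fs)
    vel, _ = differentiate(qf, fs)
    speed = np.abs(vel)

    i0 = int(np.searchsorted(t, trial.target_onset))
    i1 = int(np.searchsorted(t, trial.target_onset + SEGMENT_WINDOW_S))
    window = slice(i0, min(i1, len(t)))
    sp = speed[window]
    if sp.size == 0 or sp.max() < PEAK_SPEED_FLOOR:
        return []
    thr = SPEED_THRESHOLD_FRACTION * sp.max()
    segments = []
    for a, b in _threshold_regions(sp, thr):
        ia, ib = i0 + a, i0 + b
        if ib - ia < 3:
            continue
        if speed[ia:ib + 1].max() < PEAK_SPEED_FLOOR:
            continue
        amp = qf[ib] - qf[ia]
        seg = MovementSegment(
            t_start=float(t[ia]), t_end=float(t[ib]), amplitude=float(amp),
            peak_velocity=float(speed[ia:ib + 1].max()),
            direction="extension" if amp >= 0 else "flexion",
            target_index=getattr(trial, "target_index", None),
        )
        if getattr(trial, "tau_interaction", None) is not None:
            seg.mean_abs_tau_i = mean_abs_interaction_torque(seg, trial)
        if ib - ia + 1 >= 32:
            seg.smoothness = spectral_smoothness(vel[ia:ib + 1], fs)
        segments.append(seg)
    return segments


def reaction_time(trial, channel: str = "q", prefiltered: bool = False):
    """Time from target onset to the first sample with speed > 0.01 rad/s.

    Returns NaN (with a warning) when the speed never crosses the threshold.
    """
    q = getattr(trial, channel)
    fs = trial.sample_rate
    qf = q if prefiltered else filter_position(q, fs)
    vel, _ = differentiate(qf, fs)
    mask = (trial.t >= trial.target_onset) & (np.abs(vel) > REACTION_SPEED_THRESHOLD)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn("no supra-threshold velocity after target onset")
        return float("nan")
    return float(trial.t[idx[0]] - trial.target_onset)


def _ols_on_means(amplitudes: np.ndarray, durations: np.ndarray) -> AmplitudeDurationFit:
    n = len(amplitudes)
    if n < 2:
        raise ValueError("need at least two targets for an affine fit")
    if np.allclose(durations, durations[0]):
        return AmplitudeDurationFit(slope=0.0, intercept=float(durations[0]),
                                    r_squared=0.0, n_points=n, degenerate=True)
    slope, intercept = np.polyfit(amplitudes, durations, 1)
    pred = slope * amplitudes + intercept
    ss_res = float(np.sum((durations - pred) ** 2))
    ss_tot = float(np.sum((durations - durations.mean()) ** 2))
    return AmplitudeDurationFit(slope=float(slope), intercept=float(intercept),
                                r_squared=1.0 - ss_res / ss_tot, n_points=n)


def fit_amplitude_duration(segments_by_target: dict) -> AmplitudeDurationFit:
    """Per-target means of |amplitude| and duration, then ordinary least squares.

    ``segments_by_target`` maps a target key to its list of MovementSegment
    (flexions and extensions pooled).
    """
    amps, durs = [], []
    for key in sorted(segments_by_target):
        segs = segments_by_target[key]
        if not segs:
            continue
        amps.append(np.mean([abs(s.amplitude) for s in segs]))
        durs.append(np.mean([s.duration for s in segs]))
    return _ols_on_means(np.asarray(amps), np.asarray(durs))


def fit_amplitude_duration_group(per_participant_means: pd.DataFrame) -> AmplitudeDurationFit:
    """Group-level fit: average per-participant per-target means, then OLS.

    Expects columns (participant, target, amplitude, duration).
    """
    g = per_participant_means.groupby("target")[["amplitude", "duration"]].mean()
    return _ols_on_means(g["amplitude"].to_numpy(), g["duration"].to_numpy())


def mean_abs_interaction_torque(segment: MovementSegment, trial) -> float:
    """Time-average of |tau_interaction| over the segment span."""
    tau = getattr(trial, "tau_interaction", None)
    if tau is None:
        raise ValueError("trial carries no interaction-torque channel")
    mask = (trial.t >= segment.t_start) & (trial.t <= segment.t_end)
    if mask.sum() < 2:
        raise ValueError("segment spans fewer than two samples")
    tt, xx = trial.t[mask], np.abs(tau[mask])
    return float(np.trapezoid(xx, tt) / (tt[-1] - tt[0]))


def spectral_smoothness(velocity: np.ndarray, sample_rate: float,
                        band_hz: float = 10.0,
                        amplitude_threshold: float = 0.05) -> float:
    """Spectral arc length of the speed profile (more negative = less smooth).

    The speed profile is zero-padded to the next power of two at least four
    times its length and its magnitude spectrum normalized to unit peak.
    The cutoff is adaptive: the highest frequency (at most ``band_hz``)
    where the normalized spectrum still exceeds ``amplitude_threshold``.
    The arc length of the normalized spectrum is accumulated up to the
    cutoff with the frequency axis normalized by it, which makes the score
    invariant to amplitude scaling and (approximately) to duration
    rescaling; submovement ripple lengthens the arc, lowering the score.
    """
    v = np.asarray(velocity, float)
    if v.size < 32:
        return float("nan")
    speed = np.abs(v)
    if speed.max() <= 0:
        return float("nan")
    n_fft = int(2 ** np.ceil(np.log2(4 * v.size)))
    mag = np.abs(np.fft.rfft(speed, n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    sel = freqs <= band_hz
    mag = mag[sel] / mag[sel].max()
    freqs = freqs[sel]
    above = np.flatnonzero(mag >= amplitude_threshold)
    i_cut = above[-1] if above.size else len(mag) - 1
    i_cut = max(i_cut, 2)
    mag = mag[:i_cut + 1]
    f_norm = freqs[:i_cut + 1] / freqs[i_cut]
    darc = np.sqrt(np.diff(f_norm) ** 2 + np.diff(mag) ** 2)
    return float(-np.sum(darc))


def segments_table(trials, segments_per_trial) -> pd.DataFrame:
    """Flatten segments into one row per movement."""
    rows = []
    for trial, segs in zip(trials, segments_per_trial):
        for s in segs:
            rows.append({
                "entity": getattr(trial, "entity_id", None),
                "condition": getattr(trial, "condition", None),
                "target_index": s.target_index,
                "t_start": s.t_start, "t_end": s.t_end,
                "duration": s.duration, "amplitude": s.amplitude,
                "peak_velocity": s.peak_velocity, "direction": s.direction,
                "mean_abs_tau_i": s.mean_abs_tau_i, "smoothness": s.smoothness,
            })
    return pd.DataFrame(rows)
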