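"""Kinematic preprocessing: filtering, differentiation, segmentation,
reaction time, affine fits, torque summaries, and spectral smoothness."""

import numpy as np
import pandas as pd
import pytest

from dyadvigor import (SessionConfig, SubjectProfile, differentiate,
                       filter_position, fit_amplitude_duration,
                       generate_solo_session,
                       mean_abs_interaction_torque, reaction_time,
                       segment_movements, spectral_smoothness)
from dyadvigor.kinematics import (AmplitudeDurationFit, MovementSegment,
                                  fit_amplitude_duration_group)
from dyadvigor.params import AD_LAW_AVERAGE
from dyadvigor.synthetic import TrialTimeSeries

FS = 300.0


def _trial(q, onset=0.5, fs=FS, tau=None):
    t = np.arange(len(q)) / fs
    return TrialTimeSeries(t=t, q=np.asarray(q, float), target_onset=onset,
                           target_amplitude=1.0, direction="extension",
                           condition="NF1", sample_rate=fs, target_index=1,
                           tau_interaction=tau)


def _minimum_jerk_q(t, onset, T, A, q0=0.0):
    z = np.clip((t - onset) / T, 0, 1)
    return q0 + A * z ** 3 * (10 - 15 * z + 6 * z ** 2)


class TestFilterPosition:
    def test_dc_gain_is_unity(self):
        q = np.full(400, 0.7)
        np.testing.assert_allclose(filter_position(q, FS), q, atol=1e-12)

    def test_passband_sinusoid_nearly_untouched(self):
        t = np.arange(0, 5, 1 / FS)
        q = np.sin(2 * np.pi * 1.0 * t)
        out = filter_position(q, FS)
        mid = slice(300, -300)
        amp = np.max(np.abs(out[mid])) / np.max(np.abs(q[mid]))
        assert abs(1 - amp) < 0.01
        lag = np.argmax(np.correlate(out[mid], q[mid], "full")) - (len(q[mid]) - 1)
        assert abs(lag / FS * 360.0) < 1.0  # degrees of a 1 Hz cycle

    def test_stopband_sinusoid_removed(self):
        t = np.arange(0, 3, 1 / FS)
        q = np.sin(2 * np.pi * 30.0 * t)
        out = filter_position(q, FS)
        assert np.max(np.abs(out[200:-200])) < 0.01

    def test_idempotent_on_band_limited_signal(self):
        # integer-cycle sine with zero endpoints: the odd-extension padding
        # continues it exactly, so no edge transient enters the window
        t = np.linspace(0, 4, int(4 * FS) + 1)
        q = 0.3 * np.sin(2 * np.pi * 1.0 * t)
        once = filter_position(q, FS)
        twice = filter_position(once, FS)
        interior = slice(300, -300)  # reflected padding is not exactly LTI
        assert np.max(np.abs(twice[interior] - once[interior])) < 1e-6

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            filter_position(np.zeros(10), FS)


class TestDifferentiate:
    def test_linear_ramp(self):
        t = np.arange(200) / FS
        vel, acc = differentiate(3.0 * t, FS)
        np.testing.assert_allclose(vel, 3.0, atol=1e-9)
        np.testing.assert_allclose(acc[1:-1], 0.0, atol=1e-6)

    def test_minimum_jerk_velocity_matches_analytic(self):
        t = np.arange(0, 1.6, 1 / FS)
        T, A = 1.2, 1.0
        q = _minimum_jerk_q(t, 0.1, T, A)
        vel, _ = differentiate(q, FS)
        z = np.clip((t - 0.1) / T, 0, 1)
        v_true = (A / T) * 30 * z ** 2 * (1 - z) ** 2
        v_true[(t < 0.1) | (t > 0.1 + T)] = 0
        interior = (t > 0.12) & (t < 0.08 + T)
        assert np.max(np.abs(vel[interior] - v_true[interior])) < 1e-4

    def test_reversed_series_negates_velocity(self, rng):
        q = np.cumsum(rng.normal(size=100))
        v1, _ = differentiate(q, FS)
        v2, _ = differentiate(q[::-1], FS)
        np.testing.assert_allclose(v2, -v1[::-1], atol=1e-9)


class TestSegmentMovements:
    def test_recovers_duration_of_clean_minimum_jerk(self):
        T, A, onset = 0.6, 1.0, 0.5
        t = np.arange(0, 2.4, 1 / FS)
        tr = _trial(_minimum_jerk_q(t, onset + 0.2, T, A), onset=onset)
        segs = segment_movements(tr)
        assert len(segs) == 1
        # analytic 5%-of-peak crossings of the minimum-jerk speed profile
        z = np.linspace(0, 1, 200001)
        w = 30 * z ** 2 * (1 - z) ** 2
        above = z[w >= 0.05 * w.max()]
        expected = (above[-1] - above[0]) * T
        assert abs(segs[0].duration - expected) <= 2 / FS

    def test_no_movement_yields_no_segments(self):
        tr = _trial(np.full(900, 0.2))
        assert segment_movements(tr) == []

    def test_back_to_back_movements_split(self):
        t = np.arange(0, 2.4, 1 / FS)
        q = (_minimum_jerk_q(t, 0.6, 0.4, 0.8)
             + _minimum_jerk_q(t, 1.4, 0.4, -0.8))
        segs = segment_movements(_trial(q, onset=0.5))
        assert len(segs) == 2
        assert segs[0].t_end < segs[1].t_start
        assert {s.direction for s in segs} == {"extension", "flexion"}


class TestReactionTime:
    def test_known_latency_recovered(self):
        t = np.arange(0, 2.0, 1 / FS)
        tr = _trial(_minimum_jerk_q(t, 0.7, 0.5, 1.0), onset=0.5)
        # clean constructed trace: threshold the raw velocity (the zero-phase
        # low-pass would smear the onset backwards)
        rt = reaction_time(tr, prefiltered=True)
        assert rt == pytest.approx(0.2, abs=2 / FS + 0.01)

    def test_flat_trace_reports_missing(self):
        tr = _trial(np.zeros(900))
        with pytest.warns(UserWarning):
            assert np.isnan(reaction_time(tr))

    def test_robust_to_small_noise(self, rng):
        t = np.arange(0, 2.0, 1 / FS)
        q = _minimum_jerk_q(t, 0.7, 0.5, 1.0)
        clean = reaction_time(_trial(q, onset=0.5), prefiltered=True)
        noisy = reaction_time(_trial(q + rng.normal(0, 1e-6, len(q)), onset=0.5),
                              prefiltered=True)
        assert abs(noisy - clean) <= 2 / FS


class TestAmplitudeDurationFit:
    def test_exact_affine_points_recover_printed_law(self, amplitudes):
        segs = {}
        for k, A in enumerate(amplitudes, 1):
            T = AD_LAW_AVERAGE[0] * A + AD_LAW_AVERAGE[1]
            segs[k] = [MovementSegment(0.0, T, amplitude=A, peak_velocity=1.0,
                                       direction="extension")]
        fit = fit_amplitude_duration(segs)
        assert fit.slope == pytest.approx(0.314, abs=1e-12)
        assert fit.intercept == pytest.approx(0.298, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_durations_flagged_degenerate(self, amplitudes):
        segs = {k: [MovementSegment(0.0, 0.5, amplitude=A, peak_velocity=1.0,
                                    direction="extension")]
                for k, A in enumerate(amplitudes, 1)}
        fit = fit_amplitude_duration(segs)
        assert fit.degenerate and fit.slope == 0.0 and fit.r_squared == 0.0

    def test_single_target_rejected(self):
        with pytest.raises(ValueError):
            fit_amplitude_duration({1: [MovementSegment(
                0.0, 0.5, amplitude=0.3, peak_velocity=1.0, direction="extension")]})

    def test_noisy_means_recover_slope(self, rng, amplitudes):
        segs = {}
        for k, A in enumerate(amplitudes, 1):
            T = 0.3 * A + 0.25
            segs[k] = [MovementSegment(0.0, max(T + rng.normal(0, 0.03), 0.05),
                                       amplitude=A, peak_velocity=1.0,
                                       direction="extension")
                       for _ in range(1000)]
        fit = fit_amplitude_duration(segs)
        assert fit.slope == pytest.approx(0.3, rel=0.02)

    def test_group_fit_averages_before_regression(self, amplitudes):
        rows = []
        for p, offset in (("a", -0.05), ("b", 0.05)):
            for k, A in enumerate(amplitudes, 1):
                rows.append({"participant": p, "target": k, "amplitude": A,
                             "duration": 0.3 * A + 0.25 + offset})
        fit = fit_amplitude_duration_group(pd.DataFrame(rows))
        assert fit.slope == pytest.approx(0.3, abs=1e-9)
        assert fit.intercept == pytest.approx(0.25, abs=1e-9)


class TestInteractionTorque:
    def test_constant_torque(self):
        tau = np.full(900, 0.05)
        tr = _trial(np.zeros(900), tau=tau)
        seg = MovementSegment(0.5, 1.5, amplitude=0.5, peak_velocity=1.0,
                              direction="extension")
        assert mean_abs_interaction_torque(seg, tr) == pytest.approx(0.05)

    def test_sign_alternating_square_wave(self):
        tau = 0.1 * np.sign(np.sin(2 * np.pi * 5 * np.arange(900) / FS))
        tau[tau == 0] = 0.1
        tr = _trial(np.zeros(900), tau=tau)
        seg = MovementSegment(0.5, 1.5, amplitude=0.5, peak_velocity=1.0,
                              direction="extension")
        assert mean_abs_interaction_torque(seg, tr) == pytest.approx(0.1)

    def test_matches_quadrature_and_partner_swap(self):
        t = np.arange(900) / FS
        qf = 0.3 * np.sin(2 * np.pi * t)
        qs = 0.2 * np.sin(2 * np.pi * t + 0.5)
        kappa = 0.5
        seg = MovementSegment(0.4, 1.8, amplitude=0.5, peak_velocity=1.0,
                              direction="extension")
        tr_fs = _trial(qf, tau=kappa * (qf - qs))
        tr_sf = _trial(qs, tau=kappa * (qs - qf))
        m = (t >= 0.4) & (t <= 1.8)
        oracle = np.trapezoid(np.abs(kappa * (qf - qs))[m], t[m]) / (t[m][-1] - t[m][0])
        assert mean_abs_interaction_torque(seg, tr_fs) == pytest.approx(oracle, abs=1e-6)
        assert mean_abs_interaction_torque(seg, tr_sf) == pytest.approx(
            mean_abs_interaction_torque(seg, tr_fs), abs=1e-12)

    def test_missing_channel_rejected(self):
        tr = _trial(np.zeros(900))
        seg = MovementSegment(0.5, 1.5, amplitude=0.5, peak_velocity=1.0,
                              direction="extension")
        with pytest.raises(ValueError):
            mean_abs_interaction_torque(seg, tr)


class TestSpectralSmoothness:
    @staticmethod
    def _mj_velocity(T, fs=FS):
        t = np.arange(0, T, 1 / fs)
        z = t / T
        return 30 * z ** 2 * (1 - z) ** 2 / T

    def test_submovement_lowers_the_score(self):
        v = self._mj_velocity(0.8)
        t = np.arange(len(v)) / FS
        bumpy = v + 0.25 * np.exp(-((t - 0.6) ** 2) / (2 * 0.04 ** 2))
        assert spectral_smoothness(bumpy, FS) < spectral_smoothness(v, FS)

    def test_duration_rescaling_leaves_score_invariant(self):
        s1 = spectral_smoothness(self._mj_velocity(0.5), FS)
        s2 = spectral_smoothness(self._mj_velocity(1.0), FS)
        assert s2 == pytest.approx(s1, rel=0.02)

    def test_degenerate_inputs_report_missing(self):
        assert np.isnan(spectral_smoothness(np.zeros(64), FS))
        assert np.isnan(spectral_smoothness(np.ones(10), FS))


class TestPipelineRoundTrip:
    def test_known_affine_law_recovered_within_3pct(self):
        """Generation + segmentation + fitting recovers a known slope.

        The 5%-of-peak rule measures a fixed fraction c of the nominal
        minimum-jerk duration (the span between the analytic crossings), so
        the recovered slope estimates c * ad_slope; with duration_cv = 0.05
        and 10 trials per target the per-seed scatter is ~1 standard error,
        so the recovery check applies to the mean over 10 seeds.
        """
        z = np.linspace(0, 1, 200001)
        w = 30 * z ** 2 * (1 - z) ** 2
        above = z[w >= 0.05 * w.max()]
        c = above[-1] - above[0]
        slopes = []
        for seed in range(10):
            prof = SubjectProfile(f"s{seed}", 0.32, 0.29, duration_cv=0.05,
                                  noise_sd=0.0)
            cfg = SessionConfig(trials_per_target_per_direction=5, seed=seed,
                                quantize=False)
            trials = generate_solo_session(prof, cfg)
            segs = {}
            for tr in trials:
                for s in segment_movements(tr, prefiltered=True):
                    segs.setdefault(tr.target_index, []).append(s)
            fit = fit_amplitude_duration(segs)
            slopes.append(fit.slope)
            assert fit.slope == pytest.approx(c * prof.ad_slope, rel=0.12)
        assert np.mean(slopes) == pytest.approx(c * prof.ad_slope, rel=0.03)
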