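"""Calibration, filtering, peak finding, cycle metrics, resultant, fluency."""

import numpy as np
import pytest
from scipy.integrate import quad

from tests.conftest import sine_series
from vestkit.kinematics import (
    CalibrationUnstableError,
    InsufficientCyclesError,
    PeakList,
    UndefinedFluencyError,
    analyze_series,
    analyze_session,
    calibrate_neutral,
    compute_cycle_metrics,
    compute_fluency,
    dimensionless_jerk,
    find_extrema,
    lowpass,
    resultant_angle,
    to_relative,
)
from vestkit.prescriptions import ExercisePrescription
from vestkit.session import SessionRecord
from vestkit.synthetic import ErrorInjection, SyntheticSpec, generate_exercise_series


def constant_series(values=(2.0, -3.0, 5.0), duration=4.0, fs=50.0, noise_sd=0.0,
                    seed=0, reference="absolute"):
    n = int(duration * fs)
    rng = np.random.default_rng(seed)
    make = lambda v: np.full(n, v) + (rng.normal(0, noise_sd, n) if noise_sd else 0.0)
    from vestkit.series import AngleSeries

    return AngleSeries(
        t=np.arange(n) / fs,
        roll=make(values[0]), pitch=make(values[1]), yaw=make(values[2]),
        sample_rate_hz=fs, frame="head", reference=reference,
    )


class TestCalibration:
    def test_constant_series_exact_pose(self):
        pose = calibrate_neutral(constant_series(), window_s=2.0)
        assert (pose.roll0, pose.pitch0, pose.yaw0) == (2.0, -3.0, 5.0)
        assert pose.stability_sd_deg == 0.0

    def test_noisy_series_matches_mean_oracle(self):
        s = constant_series(noise_sd=0.1, seed=7)
        pose = calibrate_neutral(s, window_s=2.0)
        mask = s.t <= 2.0
        for attr, channel in [("roll0", s.roll), ("pitch0", s.pitch), ("yaw0", s.yaw)]:
            assert getattr(pose, attr) == pytest.approx(np.mean(channel[mask]), abs=1e-12)
        assert abs(pose.roll0 - 2.0) < 0.05

    def test_unstable_window_raises(self):
        s = constant_series(noise_sd=3.0, seed=1)
        with pytest.raises(CalibrationUnstableError):
            calibrate_neutral(s, window_s=2.0)


class TestToRelative:
    def test_zero_neutral_identity(self):
        s = constant_series()
        pose = calibrate_neutral(constant_series(values=(0, 0, 0)), 2.0)
        rel = to_relative(s, pose)
        assert np.array_equal(rel.yaw, s.yaw)
        assert rel.reference == "neutral-relative"

    def test_own_calibration_gives_zero(self):
        s = constant_series()
        rel = to_relative(s, calibrate_neutral(s, 2.0))
        assert np.allclose(rel.roll, 0) and np.allclose(rel.yaw, 0)

    def test_double_subtraction_guard(self):
        s = constant_series(reference="neutral-relative")
        with pytest.raises(ValueError, match="already"):
            to_relative(s, calibrate_neutral(constant_series(), 2.0))

    def test_offset_invariance_of_metrics(self, vor_prescription):
        lab = generate_exercise_series(
            SyntheticSpec(prescription=vor_prescription, seed=5)
        )
        base = analyze_series(lab.series, vor_prescription)
        shifted = lab.series.replace(yaw=lab.series.yaw + 10.0)
        again = analyze_series(shifted, vor_prescription)
        assert again.rom_mean_deg == pytest.approx(base.rom_mean_deg, abs=1e-9)
        assert again.freq_mean_hz == pytest.approx(base.freq_mean_hz, abs=1e-12)


class TestLowpass:
    def test_dc_gain_unity(self):
        s = constant_series()
        out = lowpass(s, 6.0)
        assert np.allclose(out.yaw, s.yaw, atol=1e-9)

    def test_passband_preserved(self):
        s = sine_series(amplitude=20, freq=1.0)
        out = lowpass(s, 6.0)
        assert np.max(np.abs(out.yaw)) > 0.99 * 20

    def test_stopband_power_removed(self):
        s = sine_series(amplitude=10, freq=1.0)
        s.yaw = s.yaw + 5 * np.sin(2 * np.pi * 15.0 * s.t)
        out = lowpass(s, 6.0)
        def power_at(x, f):
            spectrum = np.abs(np.fft.rfft(x)) ** 2
            freqs = np.fft.rfftfreq(len(x), 1 / 50.0)
            return spectrum[np.argmin(np.abs(freqs - f))]
        assert power_at(out.yaw, 15.0) < 0.1 * power_at(s.yaw, 15.0)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass(constant_series(), 30.0)


class TestFindExtrema:
    def test_pure_sinusoid_count_and_values(self):
        s = sine_series(amplitude=20, freq=1.0, duration=60.0)
        peaks = find_extrema(s.t, s.yaw, 50.0, min_prominence_deg=5, min_separation_s=0.25)
        assert peaks.n in (119, 120)  # ~2 extrema per cycle over 60 s
        assert np.all(np.abs(np.abs(peaks.values) - 20.0) < 0.2)
        assert np.all(peaks.signs[1:] * peaks.signs[:-1] == -1)

    def test_constant_channel_empty(self):
        s = constant_series()
        peaks = find_extrema(s.t, s.yaw, 50.0, 5.0, 0.25)
        assert peaks.n == 0

    def test_noise_does_not_change_count(self):
        s = sine_series(amplitude=20, freq=1.0, duration=60.0)
        clean = find_extrema(s.t, s.yaw, 50.0, 5.0, 0.25)
        rng = np.random.default_rng(11)
        noisy = find_extrema(s.t, s.yaw + rng.normal(0, 1.0, s.n_samples), 50.0, 5.0, 0.25)
        assert noisy.n == clean.n

    def test_alternation_enforced_on_same_sign_candidates(self):
        # two local maxima separated by a shallow dip (no qualifying minimum)
        t = np.arange(0, 10, 0.02)
        x = 10 * np.sin(2 * np.pi * 0.2 * t) + 3 * np.sin(2 * np.pi * 0.6 * t)
        peaks = find_extrema(t, x, 50.0, min_prominence_deg=1.0, min_separation_s=0.1)
        assert np.all(peaks.signs[1:] * peaks.signs[:-1] == -1)


class TestCycleMetrics:
    def test_ideal_alternating_extrema(self):
        times = np.arange(0, 60, 0.5)
        values = np.where(np.arange(len(times)) % 2 == 0, 20.0, -20.0)
        signs = np.where(np.arange(len(times)) % 2 == 0, 1, -1)
        m = compute_cycle_metrics(PeakList(times, values, signs), span_s=60.0)
        assert m.rom_mean_deg == 40.0
        assert m.rom_var_deg2 == 0.0
        assert m.freq_mean_hz == pytest.approx(1.0)
        assert m.freq_var_hz2 == pytest.approx(0.0, abs=1e-12)

    def test_two_extrema_insufficient(self):
        peaks = PeakList(np.array([0.0, 0.5]), np.array([20.0, -20.0]),
                         np.array([1, -1]))
        with pytest.raises(InsufficientCyclesError):
            compute_cycle_metrics(peaks, 60.0)

    def test_variances_match_direct_oracle(self, vor_prescription):
        lab = generate_exercise_series(
            SyntheticSpec.clean(vor_prescription, amplitude_jitter_frac=0.10, seed=3)
        )
        s = lab.series
        peaks = find_extrema(s.t, s.yaw, s.sample_rate_hz, 5.0, 0.25)
        m = compute_cycle_metrics(peaks, s.span_s)
        roms = np.abs(np.diff(peaks.values))
        freqs = 1.0 / (peaks.times[2:] - peaks.times[:-2])
        assert m.rom_var_deg2 == pytest.approx(np.var(roms, ddof=1), abs=1e-9)
        assert m.freq_var_hz2 == pytest.approx(np.var(freqs, ddof=1), abs=1e-12)


class TestResultant:
    def test_three_four_five(self):
        out = resultant_angle(np.full(10, 3.0), np.full(10, 4.0))
        assert np.allclose(out, 5.0)

    def test_zero_inputs(self):
        assert np.all(resultant_angle(np.zeros(5), np.zeros(5)) == 0.0)

    def test_dominates_components_pointwise(self):
        rng = np.random.default_rng(2)
        ml, ap = rng.normal(0, 3, 500), rng.normal(0, 3, 500)
        r = resultant_angle(ml, ap)
        assert np.all(r >= np.maximum(np.abs(ml), np.abs(ap)) - 1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            resultant_angle(np.zeros(5), np.zeros(6))


class TestFluency:
    def test_jerk_bursts_reduce_fluency(self, vor_prescription):
        clean = generate_exercise_series(SyntheticSpec.clean(vor_prescription))
        jerky = generate_exercise_series(
            SyntheticSpec.clean(
                vor_prescription,
                injections=(ErrorInjection("jerky", 10.0, 50.0, 5.0),),
            )
        )
        assert compute_fluency(clean.series.yaw, 50.0) > compute_fluency(
            jerky.series.yaw, 50.0
        )

    def test_amplitude_scale_invariance(self):
        s = sine_series(amplitude=1.0, freq=1.0, duration=10.0, fs=100.0)
        f1 = compute_fluency(s.yaw, 100.0)
        f2 = compute_fluency(2.0 * s.yaw, 100.0)
        assert f2 == pytest.approx(f1, rel=1e-6)

    def test_matches_quadrature_oracle(self):
        fs, dur = 100.0, 10.0
        t = np.arange(int(dur * fs)) / fs
        x = np.sin(2 * np.pi * t)
        w = 2 * np.pi
        integral, _ = quad(lambda u: (w**3 * np.cos(w * u)) ** 2, 0, t[-1], limit=500)
        pp = x.max() - x.min()
        dj_oracle = integral * t[-1] ** 5 / pp**2
        assert dimensionless_jerk(x, fs) == pytest.approx(dj_oracle, rel=0.005)
        assert compute_fluency(x, fs) == pytest.approx(1.0 / dj_oracle, rel=0.005)

    def test_motionless_undefined(self):
        with pytest.raises(UndefinedFluencyError):
            dimensionless_jerk(np.zeros(500), 50.0)


class TestAnalyzeSession:
    def test_noiseless_vor_recovers_prescription(self, vor_prescription, clean_vor):
        m = analyze_series(clean_vor.series, vor_prescription)
        assert m.rom_mean_deg == pytest.approx(40.0, abs=0.5)
        assert m.freq_mean_hz == pytest.approx(1.0, abs=0.02)

    def test_weight_shift_frequency(self):
        p = ExercisePrescription.default("ws_ap")
        lab = generate_exercise_series(SyntheticSpec.clean(p))
        m = analyze_series(lab.series, p)
        assert m.freq_mean_hz == pytest.approx(0.25, abs=0.01)
        assert m.rom_mean_deg == pytest.approx(20.0, abs=0.5)

    def test_single_leg_stillness_flagged(self):
        p = ExercisePrescription.default("sls_left")
        lab = generate_exercise_series(SyntheticSpec.clean(p, wander_rms_deg=0.0))
        m = analyze_series(lab.series, p)
        assert m.resultant_rom_deg == 0.0
        assert m.fluency is None and not m.fluency_defined

    def test_record_pipeline_attaches_metrics_idempotently(self, vor_record):
        once = analyze_session(vor_record)
        twice = analyze_session(once)
        assert once.metrics == twice.metrics
        assert vor_record.metrics is None  # input not mutated

    def test_error_carries_exercise_context(self, vor_prescription):
        s = sine_series(amplitude=20, freq=1.0, duration=60.0, reference="absolute")
        with pytest.raises(CalibrationUnstableError, match="vor_yaw"):
            analyze_session(
                SessionRecord("S9", "app", vor_prescription, s)
            )
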