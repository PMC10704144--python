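"""Synthetic exercise-performance signals with labeled ground truth.

No raw recordings of the study this toolkit models are publicly deposited, so
every downstream stage (kinematics, error detection, games, statistics) is
exercised against signals generated here: quasi-periodic oscillation at the
prescribed amplitude and frequency with per-half-cycle amplitude/frequency
jitter, additive Gaussian sensor noise, slow linear drift, an initial
hold-still calibration segment, and — optionally — injected, labeled error
episodes (overshoot, speed-up, jerk bursts, off-plane chin motion).

The generator emulates the statistical structure of exercise performance,
not vestibular physiology: cycle-to-cycle variability is modelled as
independent clipped-Gaussian jitter (clipped at +-2 sigma — bounded human
variability, so clean signals cannot stray past detector thresholds), noise
is white per channel, and drift is linear.  Single-leg stance, where the
prescription is stillness, is modelled as band-limited random wander of the
pelvic angles with a configurable RMS tilt.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .prescriptions import ExercisePrescription
from .series import AngleSeries
from .session import SessionRecord

INJECTION_TYPES = ("too_far", "too_fast", "jerky", "chin_motion")

_COMPASS = np.array(
    [
        (0.0, 1.0), (np.sqrt(0.5), np.sqrt(0.5)), (1.0, 0.0),
        (np.sqrt(0.5), -np.sqrt(0.5)), (0.0, -1.0),
        (-np.sqrt(0.5), -np.sqrt(0.5)), (-1.0, 0.0),
        (-np.sqrt(0.5), np.sqrt(0.5)),
    ]
)


@dataclass(frozen=True)
class ErrorInjection:
    """A labeled error episode to superimpose on a generated trial.

    ``magnitude`` is type-specific: overshoot in degrees past the prescribed
    amplitude (``too_far``); frequency multiplier (``too_fast``); jerk-burst
    amplitude in degrees (``jerky``); off-plane peak-to-peak in degrees
    (``chin_motion``).
    """

    error_type: str
    t_start: float
    t_end: float
    magnitude: float
    seed: int = 0  # burst placement for jerky injections

    def __post_init__(self) -> None:
        if self.error_type not in INJECTION_TYPES:
            raise ValueError(f"unknown error type {self.error_type!r}")
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")
        if self.t_start < 0:
            raise ValueError("t_start must be >= 0")
        if not self.magnitude > 0:
            raise ValueError("magnitude must be > 0")


@dataclass
class SyntheticSpec:
    """Everything the generator needs; the seed fixes all randomness.

    ``performed_amplitude_deg`` / ``performed_frequency_hz`` let a cohort
    simulation give each subject an achieved amplitude and pace that differs
    from what was prescribed; they default to the prescription values.
    """

    prescription: ExercisePrescription
    waveform: str = "sinusoid"              # or "triangle"
    noise_sd_deg: float = 0.5
    drift_deg_per_min: float = 0.5
    amplitude_jitter_frac: float = 0.05
    frequency_jitter_frac: float = 0.03
    sample_rate_hz: float = 50.0
    seed: int = 0
    injections: Sequence[ErrorInjection] = field(default_factory=tuple)
    calibration_hold_s: float = 2.0
    neutral_deg: tuple = (0.0, 0.0, 0.0)    # (roll0, pitch0, yaw0)
    wander_rms_deg: float = 1.5             # single-leg stance only
    wander_bandwidth_hz: float = 0.5
    performed_amplitude_deg: Optional[float] = None
    performed_frequency_hz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.waveform not in ("sinusoid", "triangle"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.noise_sd_deg < 0:
            raise ValueError("noise_sd_deg must be >= 0")
        if not 0 <= self.amplitude_jitter_frac < 1:
            raise ValueError("amplitude_jitter_frac must be in [0, 1)")
        if not 0 <= self.frequency_jitter_frac < 1:
            raise ValueError("frequency_jitter_frac must be in [0, 1)")
        if self.wander_rms_deg < 0:
            raise ValueError("wander_rms_deg must be >= 0")
        duration = self.prescription.duration_s
        for inj in self.injections:
            if inj.t_end > duration + 1e-9:
                raise ValueError(
                    f"injection interval [{inj.t_start}, {inj.t_end}] outside "
                    f"trial duration {duration} s"
                )

    @classmethod
    def clean(cls, prescription: ExercisePrescription, **overrides) -> "SyntheticSpec":
        """Disturbance-free spec: no noise, jitter, drift, or hold segment.

        The result is marked neutral-relative (it is, by construction), so it
        feeds games and detectors directly.
        """
        params = dict(
            noise_sd_deg=0.0,
            drift_deg_per_min=0.0,
            amplitude_jitter_frac=0.0,
            frequency_jitter_frac=0.0,
            calibration_hold_s=0.0,
            wander_rms_deg=0.0,
        )
        params.update(overrides)
        return cls(prescription=prescription, **params)

    @property
    def amplitude_deg(self) -> float:
        if self.performed_amplitude_deg is not None:
            return self.performed_amplitude_deg
        return self.prescription.amplitude_deg

    @property
    def frequency_hz(self) -> float:
        if self.performed_frequency_hz is not None:
            return self.performed_frequency_hz
        return self.prescription.frequency_hz


@dataclass
class LabeledSeries:
    """A generated series plus its ground truth (for tests and scoring)."""

    series: AngleSeries
    truth: list                      # (error_type, t_start, t_end) tuples
    truth_amplitude_deg: float
    truth_frequency_hz: float
    prescription: ExercisePrescription

    def truth_dicts(self) -> list[dict]:
        return [
            {"error_type": e, "t_start": a, "t_end": b} for (e, a, b) in self.truth
        ]


def _clipped_normal(rng: np.random.Generator, n: int, clip: float = 2.0) -> np.ndarray:
    return np.clip(rng.standard_normal(n), -clip, clip)


def _add_jerk_bursts(
    x: np.ndarray, t: np.ndarray, t0: float, t1: float, magnitude: float, seed: int,
    width_s: float = 0.05,
) -> None:
    """Superimpose short Gaussian-bump transients (~1 per second) in-place."""
    rng = np.random.default_rng(2_000_003 + seed)
    n_bursts = max(2, int(round(t1 - t0)))
    centers = t0 + (np.arange(n_bursts) + 0.5) * (t1 - t0) / n_bursts
    centers = centers + rng.uniform(-0.1, 0.1, n_bursts)
    signs = rng.choice((-1.0, 1.0), n_bursts)
    for c, s in zip(centers, signs):
        x += s * magnitude * np.exp(-0.5 * ((t - c) / width_s) ** 2) * (
            (t >= t0) & (t < t1)
        )


def _add_chin_motion(
    off: np.ndarray, t: np.ndarray, t0: float, t1: float, magnitude: float, freq_hz: float
) -> None:
    """Superimpose off-plane oscillation of peak-to-peak *magnitude* in-place."""
    f = freq_hz if freq_hz > 0 else 1.0
    mask = (t >= t0) & (t < t1)
    off[mask] += 0.5 * magnitude * np.sin(2.0 * np.pi * f * (t[mask] - t0))


def _waveform(phase: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sinusoid":
        return np.sin(phase)
    return sps.sawtooth(phase + np.pi / 2.0, width=0.5)


def _band_limited_wander(
    rng: np.random.Generator, n: int, fs: float, rms_deg: float, bandwidth_hz: float
) -> np.ndarray:
    if rms_deg == 0.0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sos = sps.butter(2, bandwidth_hz, btype="low", fs=fs, output="sos")
    slow = sps.sosfiltfilt(sos, white)
    sd = np.std(slow)
    return slow * (rms_deg / sd) if sd > 0 else np.zeros(n)


def generate_exercise_series(spec: SyntheticSpec) -> LabeledSeries:
    """Generate one labeled exercise trial; deterministic under ``spec.seed``.

    The primary channel (yaw for vor_yaw, pitch for vor_pitch, ML and/or AP
    pelvic lean for weight shift) oscillates at the performed amplitude and
    frequency with per-half-cycle jitter; single-leg trials wander instead of
    oscillating.  Off-axis channels carry only noise/drift unless an
    injection adds motion.  ``too_far`` / ``too_fast`` injections scale the
    amplitude / phase-advance inside their interval; ``jerky`` and
    ``chin_motion`` superimpose transients and off-plane oscillation.
    """
    p = spec.prescription
    fs = spec.sample_rate_hz
    duration = p.duration_s
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("trial too short")
    t = np.arange(n) / fs
    rng = np.random.default_rng(spec.seed)
    hold = min(spec.calibration_hold_s, duration)

    A = spec.amplitude_deg
    f0 = spec.frequency_hz
    roll = np.zeros(n)
    pitch = np.zeros(n)
    yaw = np.zeros(n)
    channels = {"roll": roll, "pitch": pitch, "yaw": yaw}

    if p.is_single_leg:
        osc = slice(0, 0)
        for name in ("roll", "pitch"):
            channels[name][:] = _band_limited_wander(
                rng, n, fs, spec.wander_rms_deg, spec.wander_bandwidth_hz
            )
    elif f0 > 0 and A > 0:
        # per-half-cycle amplitude and instantaneous-frequency profiles
        f_inst = np.zeros(n)
        A_inst = np.zeros(n)
        direction = np.zeros((n, 2))  # ws_omni only: (ML, AP) unit vector
        omni_order: list[int] = []
        start = hold
        half_index = 0
        while start < duration - 1e-9:
            f_k = f0 * (1.0 + spec.frequency_jitter_frac * float(_clipped_normal(rng, 1)[0]))
            f_k = max(f_k, 0.05 * f0)
            A_k = A * (1.0 + spec.amplitude_jitter_frac * float(_clipped_normal(rng, 1)[0]))
            dur_k = 1.0 / (2.0 * f_k)
            i0 = int(np.ceil(start * fs - 1e-9))
            i1 = min(n, int(np.ceil((start + dur_k) * fs - 1e-9)))
            f_inst[i0:i1] = f_k
            A_inst[i0:i1] = A_k
            if p.exercise == "ws_omni":
                cycle = half_index // 2
                while cycle >= len(omni_order):
                    omni_order.extend(rng.permutation(8).tolist())
                direction[i0:i1] = _COMPASS[omni_order[cycle]]
            start += dur_k
            half_index += 1

        for inj in spec.injections:
            mask = (t >= inj.t_start) & (t < inj.t_end)
            if inj.error_type == "too_fast":
                f_inst[mask] *= inj.magnitude
            elif inj.error_type == "too_far":
                A_inst[mask] *= (A + inj.magnitude) / A

        phase = 2.0 * np.pi * np.cumsum(f_inst) / fs
        primary = A_inst * _waveform(phase, spec.waveform)
        primary[t < hold] = 0.0

        if p.exercise == "ws_omni":
            roll += primary * direction[:, 0]
            pitch += primary * direction[:, 1]
        else:
            channels[p.primary_channel] += primary
    else:
        raise ValueError(
            "oscillatory exercise requires positive amplitude and frequency"
        )

    # additive injections
    for inj in spec.injections:
        if inj.error_type == "jerky":
            target = channels.get(p.primary_channel, roll)
            _add_jerk_bursts(
                target, t, inj.t_start, inj.t_end, inj.magnitude,
                seed=spec.seed * 1009 + inj.seed,
            )
        elif inj.error_type == "chin_motion":
            off_name = p.off_plane_channel or "pitch"
            _add_chin_motion(
                channels[off_name], t, inj.t_start, inj.t_end, inj.magnitude, f0
            )

    # drift, noise, neutral offset
    drift = spec.drift_deg_per_min * t / 60.0
    neutral = dict(zip(("roll", "pitch", "yaw"), spec.neutral_deg))
    for name in ("roll", "pitch", "yaw"):
        channels[name] += drift
        if spec.noise_sd_deg > 0:
            channels[name] += rng.normal(0.0, spec.noise_sd_deg, n)
        channels[name] += neutral[name]

    relative = (
        hold == 0.0
        and all(v == 0.0 for v in spec.neutral_deg)
        and spec.drift_deg_per_min == 0.0
    )
    series = AngleSeries(
        t=t,
        roll=roll,
        pitch=pitch,
        yaw=yaw,
        sample_rate_hz=fs,
        frame=p.frame,
        reference="neutral-relative" if relative else "absolute",
    )
    truth = [(inj.error_type, inj.t_start, inj.t_end) for inj in spec.injections]
    return LabeledSeries(
        series=series,
        truth=truth,
        truth_amplitude_deg=A,
        truth_frequency_hz=f0,
        prescription=p,
    )


def inject_error(labeled: LabeledSeries, injection: ErrorInjection) -> LabeledSeries:
    """Superimpose one more error episode on an already generated trial.

    Modifies only ``[t_start, t_end)`` of a copy; appends to the truth list.
    ``too_far`` rescales the primary-channel amplitude, ``too_fast`` locally
    rescales the phase advance (time-warp), ``jerky`` adds high-jerk
    transients, ``chin_motion`` adds off-plane oscillation.
    """
    series = labeled.series.copy()
    t = series.t
    if injection.t_end > t[-1] + 1e-9:
        raise ValueError("injection interval outside the series time span")
    p = labeled.prescription
    primary_name = p.primary_channel or "roll"
    x = series.channel(primary_name)
    mask = (t >= injection.t_start) & (t < injection.t_end)

    if injection.error_type == "too_far":
        A = labeled.truth_amplitude_deg
        x[mask] *= (A + injection.magnitude) / A
    elif injection.error_type == "too_fast":
        warped = injection.t_start + injection.magnitude * (t[mask] - injection.t_start)
        x[mask] = np.interp(np.clip(warped, t[0], t[-1]), t, x)
    elif injection.error_type == "jerky":
        _add_jerk_bursts(
            x, t, injection.t_start, injection.t_end, injection.magnitude,
            seed=injection.seed,
        )
    elif injection.error_type == "chin_motion":
        off_name = p.off_plane_channel or "pitch"
        _add_chin_motion(
            series.channel(off_name), t, injection.t_start, injection.t_end,
            injection.magnitude, labeled.truth_frequency_hz,
        )
    else:  # pragma: no cover - guarded by ErrorInjection.__post_init__
        raise ValueError(f"unknown error type {injection.error_type!r}")

    return LabeledSeries(
        series=series,
        truth=list(labeled.truth)
        + [(injection.error_type, injection.t_start, injection.t_end)],
        truth_amplitude_deg=labeled.truth_amplitude_deg,
        truth_frequency_hz=labeled.truth_frequency_hz,
        prescription=labeled.prescription,
    )


# ---------------------------------------------------------------------------
# paired cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortEffects:
    """App-vs-no-app differences in how subjects perform, plus subject spread.

    Shifts/scales apply to the **no-app** condition (the app condition
    performs at the prescription); between-subject spreads apply to both.
    The study finding this emulates by default is *more variable pacing
    without the app*: ``noapp_freq_jitter_scale`` inflates the no-app
    cycle-frequency jitter.
    """

    noapp_freq_shift_hz: float = 0.0
    noapp_amp_shift_deg: float = 0.0
    noapp_freq_jitter_scale: float = 1.0
    noapp_amp_jitter_scale: float = 1.0
    between_subject_freq_sd_hz: float = 0.02
    between_subject_amp_sd_deg: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "noapp_freq_jitter_scale",
            "noapp_amp_jitter_scale",
            "between_subject_freq_sd_hz",
            "between_subject_amp_sd_deg",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def generate_paired_cohort(
    n_subjects: int,
    effects: CohortEffects = CohortEffects(),
    seed: int = 0,
    exercises: Sequence[str] = ("vor_yaw",),
    base_spec: Optional[SyntheticSpec] = None,
) -> list[SessionRecord]:
    """Synthetic paired cohort: one app and one no-app record per subject per
    exercise, deterministic under *seed*.

    Each subject draws an achieved amplitude and pace around the prescription
    (between-subject spread); the no-app condition additionally applies the
    effect shifts and jitter inflations.  Records carry the generated series
    (metrics are attached downstream by the kinematics module).
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects for a paired cohort")
    root = np.random.SeedSequence(seed)
    records: list[SessionRecord] = []
    for s, subj_seq in enumerate(root.spawn(n_subjects)):
        subject_id = f"S{s:03d}"
        child_seeds = subj_seq.generate_state(2 * len(exercises) + 2)
        subj_rng = np.random.default_rng(child_seeds[0])
        for e_idx, exercise in enumerate(exercises):
            prescription = ExercisePrescription.default(exercise)
            dA = float(subj_rng.normal(0.0, effects.between_subject_amp_sd_deg))
            df = float(subj_rng.normal(0.0, effects.between_subject_freq_sd_hz))
            for c_idx, condition in enumerate(("app", "no_app")):
                template = base_spec if base_spec is not None else SyntheticSpec(
                    prescription=prescription
                )
                amp = prescription.amplitude_deg + dA
                freq = prescription.frequency_hz + df
                amp_jit = template.amplitude_jitter_frac
                freq_jit = template.frequency_jitter_frac
                if condition == "no_app":
                    amp += effects.noapp_amp_shift_deg
                    freq += effects.noapp_freq_shift_hz
                    amp_jit = min(0.99, amp_jit * effects.noapp_amp_jitter_scale)
                    freq_jit = min(0.99, freq_jit * effects.noapp_freq_jitter_scale)
                if prescription.is_single_leg:
                    amp, freq = 0.0, 0.0
                spec = dataclasses.replace(
                    template,
                    prescription=prescription,
                    amplitude_jitter_frac=amp_jit,
                    frequency_jitter_frac=freq_jit,
                    seed=int(child_seeds[1 + 2 * e_idx + c_idx] % (2**31 - 1)),
                    performed_amplitude_deg=max(amp, 1.0) if not prescription.is_single_leg else None,
                    performed_frequency_hz=max(freq, 0.05) if not prescription.is_single_leg else None,
                )
                labeled = generate_exercise_series(spec)
                records.append(
                    SessionRecord(
                        subject_id=subject_id,
                        condition=condition,
                        prescription=prescription,
                        series=labeled.series,
                        extra={
                            "truth": labeled.truth_dicts(),
                            "performed": {
                                "amplitude_deg": labeled.truth_amplitude_deg,
                                "frequency_hz": labeled.truth_frequency_hz,
                            },
                            "provenance": {"cohort_seed": seed, "spec_seed": spec.seed},
                        },
                    )
                )
    return records
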