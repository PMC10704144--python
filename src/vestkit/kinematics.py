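"""Kinematic outcome metrics for vestibular-rehabilitation exercises.

Pipeline (mirroring the in-app processing): the hold-still calibration window
defines the neutral pose; angles are re-expressed relative to it; a zero-phase
low-pass filter removes sensor noise; a peak-finding step identifies the
alternating left/right (or forward/back) extrema of each oscillation cycle;
and from the extrema the trial-level outcome metrics are computed:

* range of motion (ROM) — mean and variance of the angular distance between
  consecutive alternating extrema (so a prescribed 20 deg from midline
  corresponds to an expected ROM of 40 deg peak-to-peak);
* frequency — mean and variance of per-cycle frequency, one cycle being the
  time between consecutive same-sign extrema (so a 1 Hz oscillation reads as
  1 Hz, not 2 Hz);
* for single-leg balance: the resultant pelvic angle
  ``sqrt(ML^2 + AP^2)``, its mean peak excursion, and a fluency
  (smoothness) score — the reciprocal of the dimensionless jerk, larger for
  smoother motion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .prescriptions import ExercisePrescription
from .series import AngleSeries


class CalibrationUnstableError(ValueError):
    """The hold-still calibration window was not still enough."""


class InsufficientCyclesError(ValueError):
    """Too few extrema to compute cycle metrics (need >= 3)."""


class UndefinedFluencyError(ValueError):
    """Fluency is undefined for a motionless (zero peak-to-peak) signal."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NeutralPose:
    """Neutral orientation from the hold-still calibration window (degrees)."""

    roll0: float
    pitch0: float
    yaw0: float
    stability_sd_deg: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PeakList:
    """Alternating extrema of a single neutral-relative channel."""

    times: np.ndarray    # seconds, strictly increasing
    values: np.ndarray   # degrees, neutral-relative
    signs: np.ndarray    # +1 for maxima, -1 for minima, strictly alternating

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.signs = np.asarray(self.signs, dtype=int)
        if not (self.times.shape == self.values.shape == self.signs.shape):
            raise ValueError("times, values, signs must have equal length")
        if self.n >= 2:
            if not (np.diff(self.times) > 0).all():
                raise ValueError("peak times must be strictly increasing")
            if not (self.signs[1:] * self.signs[:-1] == -1).all():
                raise ValueError("peak signs must strictly alternate")

    @property
    def n(self) -> int:
        return int(self.times.shape[0])


@dataclass(frozen=True)
class CycleMetrics:
    """Per-trial ROM and frequency summary of an oscillatory exercise."""

    rom_mean_deg: float
    rom_var_deg2: float
    freq_mean_hz: float
    freq_var_hz2: float
    n_cycles: int

    kind = "cycle"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kind"] = self.kind
        return d


@dataclass(frozen=True)
class BalanceMetrics:
    """Per-trial pelvic excursion and smoothness summary for balance tasks.

    ``fluency`` is ``None`` (flagged) when the trial was perfectly still:
    the dimensionless jerk, hence its reciprocal, is undefined at zero
    peak-to-peak amplitude.
    """

    resultant_rom_deg: float
    fluency: Optional[float]

    kind = "balance"

    @property
    def fluency_defined(self) -> bool:
        return self.fluency is not None

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "resultant_rom_deg": self.resultant_rom_deg,
            "fluency": self.fluency,
        }


def metrics_from_dict(d: dict):
    kind = d.get("kind")
    if kind == "cycle":
        return CycleMetrics(
            rom_mean_deg=float(d["rom_mean_deg"]),
            rom_var_deg2=float(d["rom_var_deg2"]),
            freq_mean_hz=float(d["freq_mean_hz"]),
            freq_var_hz2=float(d["freq_var_hz2"]),
            n_cycles=int(d["n_cycles"]),
        )
    if kind == "balance":
        fl = d.get("fluency")
        return BalanceMetrics(
            resultant_rom_deg=float(d["resultant_rom_deg"]),
            fluency=None if fl is None else float(fl),
        )
    raise ValueError(f"unknown metrics kind {kind!r}")


@dataclass(frozen=True)
class KinematicsConfig:
    """Tunable processing parameters (all angles in degrees, times in s).

    Defaults: 2 s calibration window with a 1 deg stillness tolerance;
    zero-phase 4th-order Butterworth low-pass whose cutoff adapts to the
    prescription (``4 * f_prescribed`` clamped to [2, 6] Hz — the oscillation
    needs only a few harmonics of bandwidth, and a tighter cutoff suppresses
    the noise maxima that otherwise bias peak values upward; set
    ``lowpass_hz`` to a number to fix the cutoff instead); peak prominence
    5 deg with a minimum same-sign peak separation of ``0.25 / f_prescribed``
    seconds; balance-peak prominence 0.5 deg.
    """

    calibration_window_s: float = 2.0
    stability_tol_deg: float = 1.0
    lowpass_hz: Optional[float] = None  # None = adaptive to prescription
    min_prominence_deg: float = 5.0
    min_separation_factor: float = 0.25  # seconds = factor / f_prescribed
    balance_prominence_deg: float = 0.5


DEFAULT_CONFIG = KinematicsConfig()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def calibrate_neutral(
    series: AngleSeries,
    window_s: float = DEFAULT_CONFIG.calibration_window_s,
    stability_tol_deg: float = DEFAULT_CONFIG.stability_tol_deg,
) -> NeutralPose:
    """Per-channel mean over the first *window_s* seconds of an absolute series.

    Raises :class:`CalibrationUnstableError` when any channel's standard
    deviation over the window exceeds *stability_tol_deg* (the participant
    did not hold still).
    """
    if series.reference != "absolute":
        raise ValueError("calibration requires an absolute-referenced series")
    if window_s > series.span_s:
        raise ValueError("calibration window longer than the series")
    mask = series.t <= series.t[0] + window_s
    means = {c: float(np.mean(series.channel(c)[mask])) for c in ("roll", "pitch", "yaw")}
    sds = [float(np.std(series.channel(c)[mask])) for c in ("roll", "pitch", "yaw")]
    stability = max(sds)
    if stability > stability_tol_deg:
        raise CalibrationUnstableError(
            f"calibration window not still: max channel SD {stability:.3g} deg "
            f"exceeds tolerance {stability_tol_deg:g} deg"
        )
    return NeutralPose(
        roll0=means["roll"], pitch0=means["pitch"], yaw0=means["yaw"],
        stability_sd_deg=stability,
    )


def to_relative(series: AngleSeries, neutral: NeutralPose) -> AngleSeries:
    """Shift each channel by its neutral value; flips the reference flag.

    Guards against double subtraction: an already neutral-relative input is
    an error.
    """
    if series.reference != "absolute":
        raise ValueError("series is already neutral-relative")
    return series.replace(
        roll=series.roll - neutral.roll0,
        pitch=series.pitch - neutral.pitch0,
        yaw=series.yaw - neutral.yaw0,
        reference="neutral-relative",
    )


def lowpass(series: AngleSeries, cutoff_hz: float = 6.0) -> AngleSeries:
    """Zero-phase low-pass (4th-order Butterworth, applied forward-backward)."""
    nyq = series.sample_rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz:g} Hz must be below Nyquist {nyq:g} Hz")
    return series.replace(
        roll=lowpass_channel(series.roll, series.sample_rate_hz, cutoff_hz),
        pitch=lowpass_channel(series.pitch, series.sample_rate_hz, cutoff_hz),
        yaw=lowpass_channel(series.yaw, series.sample_rate_hz, cutoff_hz),
    )


def lowpass_channel(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase low-pass of one channel (order 2 each way = 4th order net)."""
    if cutoff_hz >= fs / 2.0:
        raise ValueError("cutoff must be below Nyquist")
    sos = sps.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def find_extrema(
    t: np.ndarray,
    x: np.ndarray,
    sample_rate_hz: float,
    min_prominence_deg: float = DEFAULT_CONFIG.min_prominence_deg,
    min_separation_s: float = 0.25,
) -> PeakList:
    """Alternating maxima/minima of a neutral-relative channel.

    Maxima and minima are found separately (prominence and same-sign
    separation constraints), merged in time order, and alternation is
    enforced by keeping the larger-magnitude one of any two adjacent
    same-sign candidates.  A constant channel yields an empty list.
    """
    distance = max(1, int(round(min_separation_s * sample_rate_hz)))
    hi, _ = sps.find_peaks(x, prominence=min_prominence_deg, distance=distance)
    lo, _ = sps.find_peaks(-x, prominence=min_prominence_deg, distance=distance)
    idx = np.concatenate([hi, lo])
    signs = np.concatenate([np.ones(len(hi), dtype=int), -np.ones(len(lo), dtype=int)])
    order = np.argsort(idx, kind="stable")
    idx, signs = idx[order], signs[order]

    keep_idx: list[int] = []
    keep_sign: list[int] = []
    for i, s in zip(idx, signs):
        if keep_sign and keep_sign[-1] == s:
            # adjacent same-sign candidates: keep the larger magnitude
            if abs(x[i]) > abs(x[keep_idx[-1]]):
                keep_idx[-1] = int(i)
        else:
            keep_idx.append(int(i))
            keep_sign.append(int(s))
    keep = np.asarray(keep_idx, dtype=int)
    return PeakList(
        times=t[keep] if len(keep) else np.empty(0),
        values=x[keep] if len(keep) else np.empty(0),
        signs=np.asarray(keep_sign, dtype=int),
    )


def compute_cycle_metrics(peaks: PeakList, span_s: float) -> CycleMetrics:
    """ROM and frequency statistics from an alternating extrema list.

    ROM_i is the angular distance between consecutive alternating extrema;
    a cycle is the interval between consecutive same-sign extrema.  Variances
    are sample variances (ddof=1; 0 when only one observation).
    """
    if peaks.n < 3:
        raise InsufficientCyclesError(
            f"need at least 3 extrema for cycle metrics, got {peaks.n}"
        )
    roms = np.abs(np.diff(peaks.values))
    periods = peaks.times[2:] - peaks.times[:-2]
    freqs = 1.0 / periods
    return CycleMetrics(
        rom_mean_deg=float(np.mean(roms)),
        rom_var_deg2=float(np.var(roms, ddof=1)) if len(roms) > 1 else 0.0,
        freq_mean_hz=float(np.mean(freqs)),
        freq_var_hz2=float(np.var(freqs, ddof=1)) if len(freqs) > 1 else 0.0,
        n_cycles=int(len(freqs)),
    )


def resultant_angle(ml: np.ndarray, ap: np.ndarray) -> np.ndarray:
    """Pointwise resultant pelvic angle ``sqrt(ML^2 + AP^2)`` (degrees, >= 0)."""
    ml = np.asarray(ml, dtype=float)
    ap = np.asarray(ap, dtype=float)
    if ml.shape != ap.shape:
        raise ValueError("ML and AP channels must have equal length")
    return np.hypot(ml, ap)


def _derivative(y: np.ndarray, dt: float) -> np.ndarray:
    """First time-derivative, 4th-order accurate including the boundaries.

    Boundary accuracy matters here because the derivative is applied three
    times in a row: lower-order one-sided stencils leave edge errors that
    dominate the squared-jerk integral.
    """
    d = np.empty_like(y)
    d[2:-2] = (-y[4:] + 8 * y[3:-1] - 8 * y[1:-3] + y[:-4]) / (12 * dt)
    d[0] = (-25 * y[0] + 48 * y[1] - 36 * y[2] + 16 * y[3] - 3 * y[4]) / (12 * dt)
    d[1] = (-3 * y[0] - 10 * y[1] + 18 * y[2] - 6 * y[3] + y[4]) / (12 * dt)
    d[-2] = (3 * y[-1] + 10 * y[-2] - 18 * y[-3] + 6 * y[-4] - y[-5]) / (12 * dt)
    d[-1] = (25 * y[-1] - 48 * y[-2] + 36 * y[-3] - 16 * y[-4] + 3 * y[-5]) / (12 * dt)
    return d


def dimensionless_jerk(x: np.ndarray, sample_rate_hz: float) -> float:
    """Dimensionless jerk: ``integral(j^2) * T^5 / amplitude_pp^2``.

    ``j`` is the third time-derivative of the signal, ``T`` the signal
    duration, and ``amplitude_pp`` the peak-to-peak excursion.
    Amplitude-scale invariant; larger = jerkier.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 samples for a third derivative")
    dt = 1.0 / sample_rate_hz
    pp = float(np.max(x) - np.min(x))
    if pp <= 0.0:
        raise UndefinedFluencyError("zero peak-to-peak amplitude")
    jerk = _derivative(_derivative(_derivative(x, dt), dt), dt)
    integral = float(np.trapezoid(jerk**2, dx=dt))
    duration = (x.size - 1) * dt
    return integral * duration**5 / pp**2


def compute_fluency(x: np.ndarray, sample_rate_hz: float) -> float:
    """Smoothness score: reciprocal of the dimensionless jerk.

    Amplitude-scale invariant; strictly larger for smoother motion.
    Raises :class:`UndefinedFluencyError` for a motionless signal.
    """
    if np.asarray(x).size < 2 * sample_rate_hz:
        raise ValueError("need at least 2 s of data to score fluency")
    return 1.0 / dimensionless_jerk(x, sample_rate_hz)


# ---------------------------------------------------------------------------
# session-level pipeline
# ---------------------------------------------------------------------------


def effective_cutoff_hz(prescription: ExercisePrescription,
                        config: KinematicsConfig = DEFAULT_CONFIG) -> float:
    """Low-pass cutoff for a trial: explicit, or adaptive to the prescription."""
    if config.lowpass_hz is not None:
        return config.lowpass_hz
    f = prescription.frequency_hz
    return min(max(4.0 * f, 2.0), 6.0) if f > 0 else 2.0


def preprocess(series: AngleSeries, prescription: ExercisePrescription,
               config: KinematicsConfig = DEFAULT_CONFIG) -> AngleSeries:
    """Calibrate (if needed), re-reference, and low-pass a recorded series."""
    out = series
    if out.reference == "absolute":
        neutral = calibrate_neutral(
            out, config.calibration_window_s, config.stability_tol_deg
        )
        out = to_relative(out, neutral)
    return lowpass(out, effective_cutoff_hz(prescription, config))


def analyze_series(series: AngleSeries, prescription: ExercisePrescription,
                   config: KinematicsConfig = DEFAULT_CONFIG):
    """Metrics for one recorded exercise trial.

    VOR and single-axis weight-shift trials yield :class:`CycleMetrics` from
    the prescription's primary channel; omnidirectional weight-shift and
    single-leg trials yield :class:`BalanceMetrics` from the resultant
    pelvic angle.
    """
    rel = preprocess(series, prescription, config)
    channel_name = prescription.primary_channel
    if channel_name is not None:
        x = rel.channel(channel_name)
        f = prescription.frequency_hz if prescription.frequency_hz > 0 else 1.0
        peaks = find_extrema(
            rel.t, x, rel.sample_rate_hz,
            min_prominence_deg=config.min_prominence_deg,
            min_separation_s=config.min_separation_factor / f,
        )
        try:
            return compute_cycle_metrics(peaks, rel.span_s)
        except InsufficientCyclesError as exc:
            raise InsufficientCyclesError(
                f"{prescription.exercise}: {exc}"
            ) from exc

    resultant = resultant_angle(rel.ml, rel.ap)
    pk, _ = sps.find_peaks(resultant, prominence=config.balance_prominence_deg)
    rom = float(np.mean(resultant[pk])) if len(pk) else 0.0
    try:
        fluency = compute_fluency(resultant, rel.sample_rate_hz)
    except UndefinedFluencyError:
        fluency = None
    return BalanceMetrics(resultant_rom_deg=rom, fluency=fluency)


def analyze_session(record, config: KinematicsConfig = DEFAULT_CONFIG):
    """Return *record* with metrics attached (idempotent; input not mutated)."""
    try:
        metrics = analyze_series(record.series, record.prescription, config)
    except (CalibrationUnstableError, InsufficientCyclesError) as exc:
        raise type(exc)(
            f"subject {record.subject_id!r}, exercise "
            f"{record.prescription.exercise}: {exc}"
        ) from exc
    return record.replace(metrics=metrics)
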