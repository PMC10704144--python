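"""Windowed exercise-performance error detection and feedback.

During gaze-stabilization (VOR) exercises the app watches for four kinds of
performance mistake, every 7 seconds over the 60 s trial:

* ``too_far`` — head excursion past the prescribed amplitude from midline;
* ``too_fast`` — oscillating above the prescribed frequency;
* ``jerky`` — non-smooth motion (excess dimensionless jerk in the window);
* ``chin_motion`` — excess off-plane motion (pitch during a yaw exercise or
  vice versa), the signature of moving the chin instead of rotating the head.

Detection here is transparent, rule-based and per-window: each rule compares
a window statistic against a threshold expressed relative to the prescription
so the rules generalize beyond the 20 deg / 1 Hz defaults.  Each flagged
window produces at most one event per error type, each event maps to a fixed
auditory+written feedback cue, and a per-trial ledger records, per type,
whether the error was made and whether it was corrected (ceased before the
final windows of the trial).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .kinematics import (
    UndefinedFluencyError,
    dimensionless_jerk,
    find_extrema,
    lowpass_channel,
)
from .prescriptions import ExercisePrescription
from .series import AngleSeries

ERROR_TYPES = ("too_far", "too_fast", "jerky", "chin_motion")

DEFAULT_WINDOW_S = 7.0

#: fraction of a full window a terminal partial segment must reach to stand
#: on its own; shorter remainders are merged into the preceding window, so a
#: 60 s trial yields 8 windows with the last spanning 49-60 s.
PARTIAL_WINDOW_KEEP_FRAC = 2.0 / 3.0

FEEDBACK_TEXT = {
    "too_far": "Don't move your head so far",
    "too_fast": "Slow down your head movement",
    "jerky": "Keep your head movement smooth",
    "chin_motion": "Keep your chin still",
}


class ConfigurationError(ValueError):
    """Detection attempted without the required threshold configuration."""


class Window(NamedTuple):
    index: int
    t_start: float
    t_end: float


@dataclass(frozen=True)
class ErrorEvent:
    """One detected error: which window, which type, how far past threshold."""

    window_index: int
    t_start: float
    t_end: float
    error_type: str
    severity: float  # (statistic / threshold) - 1, > 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ErrorEvent":
        return cls(
            window_index=int(d["window_index"]),
            t_start=float(d["t_start"]),
            t_end=float(d["t_end"]),
            error_type=str(d["error_type"]),
            severity=float(d["severity"]),
        )


@dataclass(frozen=True)
class ErrorThresholds:
    """Per-window detection limits, expressed in prescription units.

    ``jerky_score`` is dimensionless: the window's dimensionless jerk divided
    by the ideal-sinusoid value for the prescribed frequency and window
    length, ``(2*pi*f)^6 * T^6 / 8``.  Jerk is measured on a dedicated,
    more aggressively low-passed copy of the signal (``jerk_lowpass_hz``) so
    that broadband sensor noise does not dominate the third derivative.
    """

    too_far_deg: float
    too_fast_hz: float
    jerky_score: float = 3.0
    chin_pp_deg: float = 10.0
    lowpass_hz: float = 6.0
    jerk_lowpass_hz: float = 4.0
    window_s: float = DEFAULT_WINDOW_S

    def __post_init__(self) -> None:
        for name in ("too_far_deg", "too_fast_hz", "jerky_score", "chin_pp_deg"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_prescription(
        cls,
        prescription: ExercisePrescription,
        far_factor: float = 1.25,
        fast_factor: float = 1.25,
        **overrides,
    ) -> "ErrorThresholds":
        """Default limits: 1.25x the prescribed amplitude and frequency."""
        return cls(
            too_far_deg=far_factor * prescription.amplitude_deg,
            too_fast_hz=fast_factor * prescription.frequency_hz,
            **overrides,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class FeedbackMessage:
    error_type: str
    text: str
    modality: str = "both"  # auditory + written


@dataclass
class ErrorSummary:
    """Per-trial made / corrected / not-corrected ledger plus window raster."""

    n_windows: int
    made: dict
    corrected: dict
    not_corrected: dict
    window_grid: dict  # type -> list of per-window booleans

    def to_dict(self) -> dict:
        return {
            "n_windows": self.n_windows,
            "made": dict(self.made),
            "corrected": dict(self.corrected),
            "not_corrected": dict(self.not_corrected),
            "window_grid": {k: list(map(bool, v)) for k, v in self.window_grid.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ErrorSummary":
        return cls(
            n_windows=int(d["n_windows"]),
            made={k: bool(v) for k, v in d["made"].items()},
            corrected={k: bool(v) for k, v in d["corrected"].items()},
            not_corrected={k: bool(v) for k, v in d["not_corrected"].items()},
            window_grid={k: list(map(bool, v)) for k, v in d["window_grid"].items()},
        )


@dataclass
class ErrorReport:
    """Events + summary bundle attached to a session record."""

    events: list
    summary: ErrorSummary
    thresholds: Optional[ErrorThresholds] = None

    def to_dict(self) -> dict:
        return {
            "events": [e.to_dict() for e in self.events],
            "summary": self.summary.to_dict(),
            "thresholds": self.thresholds.to_dict() if self.thresholds else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ErrorReport":
        thr = d.get("thresholds")
        return cls(
            events=[ErrorEvent.from_dict(e) for e in d["events"]],
            summary=ErrorSummary.from_dict(d["summary"]),
            thresholds=ErrorThresholds(**thr) if thr else None,
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def window_series(series: AngleSeries, window_s: float = DEFAULT_WINDOW_S) -> list[Window]:
    """Contiguous non-overlapping detection windows from the trial start.

    A terminal partial window stands on its own only when it covers at least
    :data:`PARTIAL_WINDOW_KEEP_FRAC` of a full window; shorter remainders are
    merged into the preceding window (a 60 s trial gives 8 windows, the last
    spanning 49-60 s).  A series shorter than half a window is an error.
    """
    if not window_s > 0:
        raise ValueError("window_s must be positive")
    span = series.span_s
    if span < window_s / 2.0:
        raise ValueError(
            f"series span {span:.3g} s shorter than half a window ({window_s / 2:.3g} s)"
        )
    n_full = int(span // window_s)
    remainder = span - n_full * window_s
    if n_full == 0:
        return [Window(0, 0.0, span)]
    edges = [i * window_s for i in range(n_full)]
    if remainder >= PARTIAL_WINDOW_KEEP_FRAC * window_s:
        edges.append(n_full * window_s)
    bounds = edges + [span]
    return [Window(i, bounds[i], bounds[i + 1]) for i in range(len(edges))]


def ideal_window_jerk(frequency_hz: float, window_duration_s: float) -> float:
    """Dimensionless jerk of a pure sinusoid at *frequency_hz* over a window."""
    w = 2.0 * np.pi * frequency_hz
    return w**6 * window_duration_s**6 / 8.0


def _window_frequency(
    t: np.ndarray, x: np.ndarray, fs: float, prescribed_hz: float
) -> float:
    """Mean per-cycle frequency inside one window (0 when too few extrema)."""
    peaks = find_extrema(
        t, x, fs,
        min_prominence_deg=5.0,
        min_separation_s=0.25 / prescribed_hz if prescribed_hz > 0 else 0.25,
    )
    if peaks.n < 3:
        return 0.0
    periods = peaks.times[2:] - peaks.times[:-2]
    return float(np.mean(1.0 / periods))


def detect_errors(record, thresholds: Optional[ErrorThresholds]) -> list[ErrorEvent]:
    """Per-window rule-based error events for one VOR trial.

    Requires a neutral-relative head series and explicit thresholds.  At most
    one event per error type per window; deterministic.
    """
    if thresholds is None:
        raise ConfigurationError("detection thresholds missing")
    prescription: ExercisePrescription = record.prescription
    if not prescription.is_vor:
        raise ValueError(
            "error detection is defined for VOR exercises only, got "
            f"{prescription.exercise}"
        )
    series: AngleSeries = record.series
    if series.reference != "neutral-relative":
        raise ValueError("error detection requires a neutral-relative series")

    fs = series.sample_rate_hz
    t = series.t - series.t[0]
    primary_raw = series.channel(prescription.primary_channel)
    off_raw = series.channel(prescription.off_plane_channel)
    primary = lowpass_channel(primary_raw, fs, thresholds.lowpass_hz)
    off = lowpass_channel(off_raw, fs, thresholds.lowpass_hz)
    jerk_sig = lowpass_channel(primary_raw, fs, thresholds.jerk_lowpass_hz)

    events: list[ErrorEvent] = []
    windows = window_series(series, thresholds.window_s)
    for w in windows:
        last = w.index == len(windows) - 1
        mask = (t >= w.t_start) & ((t <= w.t_end) if last else (t < w.t_end))
        if not mask.any():
            continue
        tw = t[mask]

        def emit(error_type: str, statistic: float, threshold: float) -> None:
            if statistic > threshold:
                events.append(
                    ErrorEvent(
                        window_index=w.index,
                        t_start=w.t_start,
                        t_end=w.t_end,
                        error_type=error_type,
                        severity=statistic / threshold - 1.0,
                    )
                )

        emit("too_far", float(np.max(np.abs(primary[mask]))), thresholds.too_far_deg)
        emit(
            "too_fast",
            _window_frequency(tw, primary[mask], fs, prescription.frequency_hz),
            thresholds.too_fast_hz,
        )
        try:
            dj = dimensionless_jerk(jerk_sig[mask], fs)
            ideal = ideal_window_jerk(prescription.frequency_hz, tw[-1] - tw[0])
            emit("jerky", dj / ideal, thresholds.jerky_score)
        except (UndefinedFluencyError, ValueError):
            pass  # motionless or too-short window: no jerk statistic
        emit("chin_motion", float(np.ptp(off[mask])), thresholds.chin_pp_deg)
    return events


def feedback_for(event: ErrorEvent) -> FeedbackMessage:
    """Fixed feedback cue (auditory + written) for a detected error."""
    error_type = event.error_type if isinstance(event, ErrorEvent) else str(event)
    if error_type not in FEEDBACK_TEXT:
        raise ValueError(f"unknown error type {error_type!r}")
    return FeedbackMessage(error_type=error_type, text=FEEDBACK_TEXT[error_type])


def summarize_correction(events: Sequence[ErrorEvent], n_windows: int) -> ErrorSummary:
    """Made / corrected / not-corrected ledger for one trial.

    An error type counts as *corrected* when its last flagged window is
    followed by at least two clean windows at the end of the trial
    (last index <= n_windows - 3); otherwise it was made but not corrected.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    made, corrected, not_corrected, grid = {}, {}, {}, {}
    for etype in ERROR_TYPES:
        wins = sorted({e.window_index for e in events if e.error_type == etype})
        if wins and (wins[0] < 0 or wins[-1] >= n_windows):
            raise ValueError(f"event window index out of range for {etype}")
        flags = [i in set(wins) for i in range(n_windows)]
        m = bool(wins)
        c = m and wins[-1] <= n_windows - 3
        made[etype] = m
        corrected[etype] = c
        not_corrected[etype] = m and not c
        grid[etype] = flags
    return ErrorSummary(
        n_windows=n_windows,
        made=made,
        corrected=corrected,
        not_corrected=not_corrected,
        window_grid=grid,
    )


def cohort_error_rates(summaries: Sequence[ErrorSummary]) -> dict:
    """Fractions of subjects with errors made / corrected / not corrected.

    Returned per error type plus an ``"any"`` aggregate (an error was made
    in the trial; corrected only if every made type was corrected), so that
    ``corrected + not_corrected == made`` holds for every row.
    """
    if not summaries:
        raise ValueError("need at least one summary")
    n = len(summaries)
    out: dict = {}
    for etype in ERROR_TYPES:
        made = sum(s.made[etype] for s in summaries)
        corr = sum(s.corrected[etype] for s in summaries)
        out[etype] = {
            "made": made / n,
            "corrected": corr / n,
            "not_corrected": (made - corr) / n,
        }
    any_made = sum(any(s.made.values()) for s in summaries)
    any_corr = sum(
        any(s.made.values())
        and all(s.corrected[t] for t in ERROR_TYPES if s.made[t])
        for s in summaries
    )
    out["any"] = {
        "made": any_made / n,
        "corrected": any_corr / n,
        "not_corrected": (any_made - any_corr) / n,
    }
    return out


def raster_dataframe(summary: ErrorSummary):
    """Window-by-type boolean raster (for Fig-style plots / CSV export)."""
    import pandas as pd

    return pd.DataFrame(
        {etype: summary.window_grid[etype] for etype in ERROR_TYPES},
        index=range(summary.n_windows),
    )
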