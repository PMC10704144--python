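"""Exercise prescriptions.

A prescription is the clinician-set parameter block that drives every other
component: the synthetic generator oscillates at the prescribed amplitude and
frequency, the games derive their obstacle/coin schedules from it, and the
error detectors express their thresholds relative to it.

Prescribed defaults follow the study protocol this toolkit models:

* gaze-stabilization (VOR X1) exercises: 20 degrees of head motion from the
  midline at 1 Hz for 60 s, in the yaw then the pitch plane;
* weight-shift exercises: 120 s per direction (mediolateral, anteroposterior,
  omnidirectional);
* single-leg balance: 45 s per leg, the goal being a level pelvis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

VOR_EXERCISES = ("vor_yaw", "vor_pitch")
WEIGHT_SHIFT_EXERCISES = ("ws_ml", "ws_ap", "ws_omni")
SINGLE_LEG_EXERCISES = ("sls_left", "sls_right")
EXERCISES = VOR_EXERCISES + WEIGHT_SHIFT_EXERCISES + SINGLE_LEG_EXERCISES

#: sensor frame each exercise is recorded in
FRAME_FOR_EXERCISE = {
    **{e: "head" for e in VOR_EXERCISES},
    **{e: "pelvis" for e in WEIGHT_SHIFT_EXERCISES + SINGLE_LEG_EXERCISES},
}

#: oscillation axis (Euler channel) for exercises that have a single one.
#: Pelvis convention: roll = mediolateral lean, pitch = anteroposterior lean.
PRIMARY_CHANNEL = {
    "vor_yaw": "yaw",
    "vor_pitch": "pitch",
    "ws_ml": "roll",
    "ws_ap": "pitch",
}

#: off-plane channel watched by the chin-motion detector during VOR exercises
OFF_PLANE_CHANNEL = {"vor_yaw": "pitch", "vor_pitch": "yaw"}

_DEFAULTS = {
    "vor_yaw": dict(amplitude_deg=20.0, frequency_hz=1.0, duration_s=60.0),
    "vor_pitch": dict(amplitude_deg=20.0, frequency_hz=1.0, duration_s=60.0),
    "ws_ml": dict(amplitude_deg=10.0, frequency_hz=0.25, duration_s=120.0),
    "ws_ap": dict(amplitude_deg=10.0, frequency_hz=0.25, duration_s=120.0),
    "ws_omni": dict(amplitude_deg=10.0, frequency_hz=0.25, duration_s=120.0),
    "sls_left": dict(amplitude_deg=0.0, frequency_hz=0.0, duration_s=45.0),
    "sls_right": dict(amplitude_deg=0.0, frequency_hz=0.0, duration_s=45.0),
}


@dataclass(frozen=True)
class ExercisePrescription:
    """Clinician-set exercise parameters.

    Parameters
    ----------
    exercise
        One of :data:`EXERCISES`.
    amplitude_deg
        Target excursion from the midline, degrees.  Must be positive for
        VOR and weight-shift exercises; single-leg balance prescribes
        stillness, so 0 is allowed there.
    frequency_hz
        Target oscillation pace, cycles per second.
    angular_velocity_deg_s
        Optional mean angular speed of the sweep.  For a constant-speed
        sweep covering ``4 * amplitude_deg`` per cycle it is redundant with
        the frequency (``v = 4 A f``); when both are given they must agree
        to 1 %.
    duration_s
        Trial duration, seconds.
    """

    exercise: str
    amplitude_deg: float
    frequency_hz: float
    duration_s: float
    angular_velocity_deg_s: Optional[float] = None

    @classmethod
    def default(cls, exercise: str, **overrides) -> "ExercisePrescription":
        """Prescription with the study-protocol defaults for *exercise*."""
        if exercise not in EXERCISES:
            raise ValueError(f"unknown exercise {exercise!r}")
        params = dict(_DEFAULTS[exercise])
        params.update(overrides)
        return cls(exercise=exercise, **params)

    # -- derived views -------------------------------------------------

    @property
    def frame(self) -> str:
        return FRAME_FOR_EXERCISE[self.exercise]

    @property
    def primary_channel(self) -> Optional[str]:
        return PRIMARY_CHANNEL.get(self.exercise)

    @property
    def off_plane_channel(self) -> Optional[str]:
        return OFF_PLANE_CHANNEL.get(self.exercise)

    @property
    def is_vor(self) -> bool:
        return self.exercise in VOR_EXERCISES

    @property
    def is_weight_shift(self) -> bool:
        return self.exercise in WEIGHT_SHIFT_EXERCISES

    @property
    def is_single_leg(self) -> bool:
        return self.exercise in SINGLE_LEG_EXERCISES

    def with_(self, **changes) -> "ExercisePrescription":
        return replace(self, **changes)

    # -- validation ----------------------------------------------------

    def violations(self) -> list[str]:
        """All invariant violations, as human-readable strings (never raises)."""
        out: list[str] = []
        if self.exercise not in EXERCISES:
            out.append(f"exercise: unknown exercise {self.exercise!r}")
            return out
        if not self.is_single_leg and not self.amplitude_deg > 0:
            out.append("amplitude_deg: must be > 0 for VOR/weight-shift exercises")
        if self.amplitude_deg < 0:
            out.append("amplitude_deg: must be >= 0")
        if not self.duration_s > 0:
            out.append("duration_s: must be > 0")
        if self.frequency_hz < 0:
            out.append("frequency_hz: must be >= 0")
        if self.angular_velocity_deg_s is not None:
            if self.angular_velocity_deg_s <= 0:
                out.append("angular_velocity_deg_s: must be > 0 when given")
            elif self.frequency_hz > 0 and self.amplitude_deg > 0:
                implied = self.angular_velocity_deg_s / (4.0 * self.amplitude_deg)
                if abs(implied - self.frequency_hz) > 0.01 * self.frequency_hz:
                    out.append(
                        "angular_velocity_deg_s: inconsistent with frequency_hz "
                        f"(implies {implied:.4g} rotations/s, prescribed "
                        f"{self.frequency_hz:.4g})"
                    )
        return out

    def validate(self) -> "ExercisePrescription":
        """Raise :class:`ValueError` on the first invariant violation."""
        bad = self.violations()
        if bad:
            raise ValueError("invalid prescription: " + "; ".join(bad))
        return self

    def to_dict(self) -> dict:
        d = {
            "exercise": self.exercise,
            "amplitude_deg": self.amplitude_deg,
            "frequency_hz": self.frequency_hz,
            "duration_s": self.duration_s,
        }
        if self.angular_velocity_deg_s is not None:
            d["angular_velocity_deg_s"] = self.angular_velocity_deg_s
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExercisePrescription":
        required = ("exercise", "amplitude_deg", "frequency_hz", "duration_s")
        for key in required:
            if key not in d:
                raise KeyError(key)
        return cls(
            exercise=d["exercise"],
            amplitude_deg=float(d["amplitude_deg"]),
            frequency_hz=float(d["frequency_hz"]),
            duration_s=float(d["duration_s"]),
            angular_velocity_deg_s=(
                float(d["angular_velocity_deg_s"])
                if d.get("angular_velocity_deg_s") is not None
                else None
            ),
        )
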