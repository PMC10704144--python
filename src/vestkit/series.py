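"""Orientation time series containers.

The substrate of every computation in the toolkit is an :class:`AngleSeries`:
a timestamped roll/pitch/yaw trajectory in degrees, recorded either from the
head (VOR exercises) or the pelvis (weight-shift / single-leg exercises), and
referenced either to the sensor's absolute orientation or to the hold-still
neutral pose captured at the start of the trial.

Pelvis convention throughout the toolkit: ``roll`` is the mediolateral (ML)
lean and ``pitch`` the anteroposterior (AP) lean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np
import pandas as pd

FRAMES = ("head", "pelvis")
REFERENCES = ("absolute", "neutral-relative")
CHANNELS = ("roll", "pitch", "yaw")

#: CSV header of the on-disk sample table
CSV_COLUMNS = ("t", "roll_deg", "pitch_deg", "yaw_deg")
QUAT_COLUMNS = ("qw", "qx", "qy", "qz")


@dataclass(frozen=True)
class ImuSample:
    """One orientation sample: time (s since trial start) and Euler angles (deg)."""

    t: float
    roll: float
    pitch: float
    yaw: float
    qw: Optional[float] = None
    qx: Optional[float] = None
    qy: Optional[float] = None
    qz: Optional[float] = None

    @property
    def has_quaternion(self) -> bool:
        return self.qw is not None


@dataclass
class AngleSeries:
    """Timestamped roll/pitch/yaw trajectory in degrees.

    Attributes
    ----------
    t : ndarray
        Sample times, seconds since trial start; strictly increasing, >= 0.
    roll, pitch, yaw : ndarray
        Euler angles in degrees, one value per time stamp.
    sample_rate_hz : float
        Nominal sampling rate; the median sampling interval must be within
        10 % of ``1 / sample_rate_hz``.
    frame : {"head", "pelvis"}
    reference : {"absolute", "neutral-relative"}
    quat : ndarray of shape (n, 4), optional
        Unit quaternions (w, x, y, z) when the device supplied them.
    """

    t: np.ndarray
    roll: np.ndarray
    pitch: np.ndarray
    yaw: np.ndarray
    sample_rate_hz: float
    frame: str
    reference: str
    quat: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.roll = np.asarray(self.roll, dtype=float)
        self.pitch = np.asarray(self.pitch, dtype=float)
        self.yaw = np.asarray(self.yaw, dtype=float)
        n = self.t.shape[0]
        for name in ("roll", "pitch", "yaw"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"channel {name!r} length differs from t")
        if self.quat is not None:
            self.quat = np.asarray(self.quat, dtype=float)
            if self.quat.shape != (n, 4):
                raise ValueError("quat must have shape (n_samples, 4)")

    # -- basic views ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return int(self.t.shape[0])

    @property
    def span_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.n_samples else 0.0

    @property
    def ml(self) -> np.ndarray:
        """Mediolateral pelvic lean (alias of roll)."""
        return self.roll

    @property
    def ap(self) -> np.ndarray:
        """Anteroposterior pelvic lean (alias of pitch)."""
        return self.pitch

    def channel(self, name: str) -> np.ndarray:
        if name in CHANNELS:
            return getattr(self, name)
        if name == "ml":
            return self.ml
        if name == "ap":
            return self.ap
        raise KeyError(name)

    def samples(self) -> Iterator[ImuSample]:
        for i in range(self.n_samples):
            q = self.quat[i] if self.quat is not None else (None,) * 4
            yield ImuSample(
                t=float(self.t[i]),
                roll=float(self.roll[i]),
                pitch=float(self.pitch[i]),
                yaw=float(self.yaw[i]),
                qw=q[0], qx=q[1], qy=q[2], qz=q[3],
            )

    def replace(self, **changes) -> "AngleSeries":
        return replace(self, **changes)

    def copy(self) -> "AngleSeries":
        return AngleSeries(
            t=self.t.copy(),
            roll=self.roll.copy(),
            pitch=self.pitch.copy(),
            yaw=self.yaw.copy(),
            sample_rate_hz=self.sample_rate_hz,
            frame=self.frame,
            reference=self.reference,
            quat=None if self.quat is None else self.quat.copy(),
        )

    # -- validation ----------------------------------------------------

    def violations(self) -> list[str]:
        """All invariant violations as strings; never raises."""
        out: list[str] = []
        if self.frame not in FRAMES:
            out.append(f"frame: must be one of {FRAMES}, got {self.frame!r}")
        if self.reference not in REFERENCES:
            out.append(
                f"reference: must be one of {REFERENCES}, got {self.reference!r}"
            )
        if self.n_samples < 2:
            out.append("samples: need at least 2 samples")
            return out
        if not np.isfinite(self.t).all():
            out.append("t: non-finite timestamp")
        if self.t[0] < 0:
            out.append("t: timestamps must be non-negative")
        if not (np.diff(self.t) > 0).all():
            out.append("t: timestamps must be strictly increasing")
        for name in CHANNELS:
            if not np.isfinite(getattr(self, name)).all():
                out.append(f"{name}: non-finite angle value")
        if not self.sample_rate_hz > 0:
            out.append("sample_rate_hz: must be > 0")
        else:
            dt = np.median(np.diff(self.t))
            nominal = 1.0 / self.sample_rate_hz
            if not np.isclose(dt, nominal, rtol=0.10):
                out.append(
                    "sample_rate_hz: median sampling interval "
                    f"{dt:.6g} s deviates more than 10 % from nominal {nominal:.6g} s"
                )
        if self.quat is not None:
            norms = np.linalg.norm(self.quat, axis=1)
            if not np.all(np.abs(norms - 1.0) <= 1e-6):
                out.append("quat: quaternion norm outside 1 +- 1e-6")
        return out

    def validate(self) -> "AngleSeries":
        bad = self.violations()
        if bad:
            raise ValueError("invalid series: " + "; ".join(bad))
        return self

    # -- interop -------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t": self.t,
                "roll_deg": self.roll,
                "pitch_deg": self.pitch,
                "yaw_deg": self.yaw,
            }
        )
        if self.quat is not None:
            for j, col in enumerate(QUAT_COLUMNS):
                df[col] = self.quat[:, j]
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        sample_rate_hz: float,
        frame: str,
        reference: str,
    ) -> "AngleSeries":
        quat = None
        if all(c in df.columns for c in QUAT_COLUMNS):
            quat = df[list(QUAT_COLUMNS)].to_numpy(dtype=float)
        return cls(
            t=df["t"].to_numpy(dtype=float),
            roll=df["roll_deg"].to_numpy(dtype=float),
            pitch=df["pitch_deg"].to_numpy(dtype=float),
            yaw=df["yaw_deg"].to_numpy(dtype=float),
            sample_rate_hz=sample_rate_hz,
            frame=frame,
            reference=reference,
            quat=quat,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AngleSeries):
            return NotImplemented
        if (self.frame, self.reference) != (other.frame, other.reference):
            return False
        if self.sample_rate_hz != other.sample_rate_hz:
            return False
        arrays_equal = (
            np.array_equal(self.t, other.t)
            and np.array_equal(self.roll, other.roll)
            and np.array_equal(self.pitch, other.pitch)
            and np.array_equal(self.yaw, other.yaw)
        )
        if not arrays_equal:
            return False
        if (self.quat is None) != (other.quat is None):
            return False
        return self.quat is None or np.array_equal(self.quat, other.quat)
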