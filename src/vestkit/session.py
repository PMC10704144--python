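"""On-disk session format: JSON envelope + side-car CSV of samples.

A session file stands in for the app's cloud database record: one JSON
document holding the pseudonymous subject id, the condition (``app`` /
``no_app``), the exercise prescription, and any results attached by the
analysis, detection, or game modules — plus a side-car CSV
(``<stem>.samples.csv``, header ``t,roll_deg,pitch_deg,yaw_deg``) with the
raw orientation samples.  Everything on disk is degrees and seconds since
trial start.  Unknown top-level JSON keys are preserved across a
read/write round trip but otherwise ignored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import errors as errors_mod
from . import games as games_mod
from . import kinematics
from .prescriptions import ExercisePrescription
from .series import CSV_COLUMNS, QUAT_COLUMNS, AngleSeries

SCHEMA_ID = "vestkit-session/1"
CONDITIONS = ("app", "no_app")
_RESERVED_KEYS = {
    "schema", "subject_id", "condition", "prescription", "series",
    "metrics", "errors", "game_result",
}


class SessionSchemaError(ValueError):
    """A required field is missing or malformed in the session JSON."""


class SessionParseError(ValueError):
    """The sample CSV has a malformed or non-finite row."""


class SessionValidationError(ValueError):
    """A record failed its invariants; carries the violation list."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid session record: " + "; ".join(violations))


@dataclass
class SessionRecord:
    """One exercise trial: who, which condition, what was prescribed, the data."""

    subject_id: str
    condition: str
    prescription: ExercisePrescription
    series: AngleSeries
    metrics: Optional[object] = None       # CycleMetrics | BalanceMetrics
    errors: Optional[errors_mod.ErrorReport] = None
    game_result: Optional[games_mod.GameResult] = None
    extra: dict = field(default_factory=dict)

    def replace(self, **changes) -> "SessionRecord":
        return dataclasses.replace(self, **changes)


def validate_session(record: SessionRecord) -> list[str]:
    """All invariant violations of a record, as strings.  Never raises."""
    out: list[str] = []
    if not record.subject_id:
        out.append("subject_id: must be non-empty")
    if record.condition not in CONDITIONS:
        out.append(f"condition: must be one of {CONDITIONS}, got {record.condition!r}")
    out.extend(f"prescription.{v}" for v in record.prescription.violations())
    out.extend(f"series.{v}" for v in record.series.violations())
    if record.prescription.exercise in dict.fromkeys(
        ("vor_yaw", "vor_pitch", "ws_ml", "ws_ap", "ws_omni", "sls_left", "sls_right")
    ):
        expected = record.prescription.frame
        if record.series.frame != expected:
            out.append(
                f"series.frame: {record.series.frame!r} inconsistent with exercise "
                f"{record.prescription.exercise!r} (expected {expected!r})"
            )
    return out


def _samples_csv_path(json_path: Path) -> Path:
    return json_path.with_name(json_path.stem + ".samples.csv")


def write_session(record: SessionRecord, path: Union[str, Path]) -> Path:
    """Write a validated record as JSON + side-car sample CSV.

    Refuses to write anything when the record violates its invariants.
    Returns the JSON path; ``read_session`` of it round-trips to an equal
    record.
    """
    path = Path(path)
    violations = validate_session(record)
    if violations:
        raise SessionValidationError(violations)

    csv_path = _samples_csv_path(path)
    doc = {
        "schema": SCHEMA_ID,
        "subject_id": record.subject_id,
        "condition": record.condition,
        "prescription": record.prescription.to_dict(),
        "series": {
            "sample_rate_hz": record.series.sample_rate_hz,
            "frame": record.series.frame,
            "reference": record.series.reference,
            "samples_csv": csv_path.name,
        },
        "metrics": record.metrics.to_dict() if record.metrics is not None else None,
        "errors": record.errors.to_dict() if record.errors is not None else None,
        "game_result": (
            record.game_result.to_dict() if record.game_result is not None else None
        ),
    }
    for key, value in record.extra.items():
        if key not in _RESERVED_KEYS:
            doc[key] = value

    record.series.to_dataframe().to_csv(csv_path, index=False)
    path.write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")
    return path


def _read_samples_csv(csv_path: Path) -> pd.DataFrame:
    if not csv_path.exists():
        raise SessionSchemaError(f"samples CSV not found: {csv_path}")
    try:
        df = pd.read_csv(csv_path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV structure
        raise SessionParseError(f"{csv_path.name}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SessionSchemaError(
            f"{csv_path.name}: missing required column(s) {', '.join(missing)}"
        )
    for col in CSV_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(values.to_numpy()))
        if bad.size:
            line = int(bad[0]) + 2  # 1-based, plus header line
            raise SessionParseError(
                f"{csv_path.name}: non-numeric or non-finite value in column "
                f"{col!r} at line {line}"
            )
        df[col] = values
    return df


def read_session(path: Union[str, Path]) -> SessionRecord:
    """Read and fully validate a session file written by :func:`write_session`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SessionParseError(f"{path.name}: invalid JSON ({exc})") from exc

    for key in ("subject_id", "condition", "prescription", "series"):
        if key not in doc:
            raise SessionSchemaError(f"missing required field {key!r}")
    series_meta = doc["series"]
    for key in ("sample_rate_hz", "frame", "reference", "samples_csv"):
        if key not in series_meta:
            raise SessionSchemaError(f"missing required field 'series.{key}'")
    try:
        prescription = ExercisePrescription.from_dict(doc["prescription"])
    except KeyError as exc:
        raise SessionSchemaError(
            f"missing required field 'prescription.{exc.args[0]}'"
        ) from exc

    df = _read_samples_csv(path.parent / series_meta["samples_csv"])
    series = AngleSeries.from_dataframe(
        df,
        sample_rate_hz=float(series_meta["sample_rate_hz"]),
        frame=str(series_meta["frame"]),
        reference=str(series_meta["reference"]),
    )

    metrics = (
        kinematics.metrics_from_dict(doc["metrics"])
        if doc.get("metrics") is not None
        else None
    )
    errs = (
        errors_mod.ErrorReport.from_dict(doc["errors"])
        if doc.get("errors") is not None
        else None
    )
    game_result = (
        games_mod.GameResult.from_dict(doc["game_result"])
        if doc.get("game_result") is not None
        else None
    )
    extra = {k: v for k, v in doc.items() if k not in _RESERVED_KEYS}

    record = SessionRecord(
        subject_id=str(doc["subject_id"]),
        condition=str(doc["condition"]),
        prescription=prescription,
        series=series,
        metrics=metrics,
        errors=errs,
        game_result=game_result,
        extra=extra,
    )
    violations = validate_session(record)
    if violations:
        raise SessionValidationError(violations)
    return record
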