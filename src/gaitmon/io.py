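"""File formats and run configuration.

Traces travel as CSV with an explicit time column (``time_s, ax, ay, az``)
so sampling uniformity is checkable and files are self-describing.
Calibration models and daily reports are JSON with a ``schema_version``
field. All writers followed by the matching reader are identity maps at the
stated precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .detect import DetectorConfig
from .summary import SummaryConfig
from .types import (
    AccelTrace,
    CalibrationModel,
    STANDARD_GRAVITY,
    ValidationError,
    validate_trace,
)

log = logging.getLogger("gaitmon")

TRACE_COLUMNS = ["time_s", "ax", "ay", "az"]
CALIBRATION_SCHEMA_VERSION = 1
REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration: detector + summary + input conventions."""

    detector: DetectorConfig = field(default_factory=DetectorConfig)
    summary: SummaryConfig = field(default_factory=SummaryConfig)
    units_in: str = "mps2"
    sample_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        if self.units_in not in ("mps2", "g"):
            raise ValidationError(f"units_in must be 'mps2' or 'g', got {self.units_in!r}")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")

    def to_dict(self) -> dict[str, Any]:
        return {
            "detector": vars(self.detector).copy(),
            "summary": vars(self.summary).copy(),
            "units_in": self.units_in,
            "sample_rate_hz": self.sample_rate_hz,
        }


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    The YAML file may contain ``detector:`` and ``summary:`` mappings and the
    top-level keys ``units_in`` and ``sample_rate_hz``. Keyword overrides
    (typically CLI flags) win over the file; unknown keys are rejected.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
    det_kwargs = dict(data.get("detector") or {})
    sum_kwargs = dict(data.get("summary") or {})
    top = {k: v for k, v in data.items() if k not in ("detector", "summary")}
    for key, value in overrides.items():
        if value is None:
            continue
        if key in DetectorConfig.__dataclass_fields__:
            det_kwargs[key] = value
        elif key in SummaryConfig.__dataclass_fields__:
            sum_kwargs[key] = value
        else:
            top[key] = value
    unknown = set(top) - {"units_in", "sample_rate_hz"}
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(
            detector=DetectorConfig(**det_kwargs),
            summary=SummaryConfig(**sum_kwargs),
            **top,
        )
    except TypeError as exc:
        raise ValidationError(str(exc)) from exc


def read_trace(
    path: str | Path,
    units_in: str = "mps2",
    sample_rate_hz: float = 100.0,
) -> AccelTrace:
    """Read a CSV trace (header ``time_s, ax, ay, az``) into an AccelTrace.

    Accelerations recorded in g are converted to m/s². The time column must
    be monotone and uniform, agreeing with the declared sampling rate to
    within 1%; the returned trace's ``t0`` is the first timestamp.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trace file {path} is missing columns: {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError(f"trace file {path} has non-monotone time column")
        nominal = 1.0 / sample_rate_hz
        if np.any(np.abs(dt - nominal) > 0.01 * nominal):
            raise ValidationError(
                f"trace file {path}: sampling deviates more than 1% "
                f"from the declared {sample_rate_hz} Hz"
            )
    scale = STANDARD_GRAVITY if units_in == "g" else 1.0
    if units_in not in ("mps2", "g"):
        raise ValidationError(f"units_in must be 'mps2' or 'g', got {units_in!r}")
    return AccelTrace(
        sample_rate_hz=sample_rate_hz,
        t0=float(t[0]),
        ax=df["ax"].to_numpy(dtype=float) * scale,
        ay=df["ay"].to_numpy(dtype=float) * scale,
        az=df["az"].to_numpy(dtype=float) * scale,
    )


def write_trace(trace: AccelTrace, path: str | Path) -> None:
    """Write a trace as CSV (m/s²), 6 significant digits of float precision."""
    validate_trace(trace)
    df = pd.DataFrame(
        {"time_s": trace.times, "ax": trace.ax, "ay": trace.ay, "az": trace.az}
    )
    df.to_csv(path, index=False, float_format="%.6g")


def write_calibration(model: CalibrationModel, path: str | Path) -> None:
    payload = {
        "schema_version": CALIBRATION_SCHEMA_VERSION,
        "subject_id": model.subject_id,
        "slope": model.slope,
        "intercept": model.intercept,
        "n_points": model.n_points,
        "rmse": model.rmse,
        "fit_date": model.fit_date,
        "cadence_range": list(model.cadence_range) if model.cadence_range else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_calibration(path: str | Path) -> CalibrationModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"calibration file {path} is not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise ValidationError(f"calibration file {path} lacks a schema_version field")
    if payload["schema_version"] != CALIBRATION_SCHEMA_VERSION:
        raise ValidationError(
            f"calibration schema version {payload['schema_version']} unsupported "
            f"(expected {CALIBRATION_SCHEMA_VERSION})"
        )
    try:
        rng = payload.get("cadence_range")
        return CalibrationModel(
            subject_id=payload["subject_id"],
            slope=payload["slope"],
            intercept=payload["intercept"],
            n_points=payload["n_points"],
            rmse=payload["rmse"],
            fit_date=payload.get("fit_date", ""),
            cadence_range=tuple(rng) if rng else None,
        )
    except KeyError as exc:
        raise ValidationError(f"calibration file {path} lacks field {exc}") from exc


def write_report(report: dict[str, Any], path: str | Path) -> None:
    payload = {"schema_version": REPORT_SCHEMA_VERSION, **report}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_report(path: str | Path) -> dict[str, Any]:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"report file {path} is not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise ValidationError(f"report file {path} lacks a schema_version field")
    return payload
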