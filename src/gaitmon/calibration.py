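"""Per-subject cadence-to-gait-speed calibration.

Ambulatory gait speed is estimated indirectly: the insole measures cadence,
and a per-subject calibration maps cadence to speed. Ground-truth speeds for
the calibration come from a timed 4 m course (two light barriers in the
original setup), emulated here by :func:`barrier_speed`. The mapping is an
ordinary least-squares straight line — the minimal model consistent with the
strong linear correlation between cadence and speed in normal walking — and
can be refit at any time with fresh samples when the relationship drifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
from scipy import stats

from .types import CalibrationModel, ValidationError

#: Length of the light-barrier course in metres.
BARRIER_DISTANCE_M = 4.0


@dataclass(frozen=True)
class CalibrationSample:
    """One training observation: measured cadence, true mean speed."""

    cadence: float
    true_speed: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.cadence) and self.cadence > 0):
            raise ValidationError(f"cadence must be positive, got {self.cadence}")
        if not (np.isfinite(self.true_speed) and self.true_speed > 0):
            raise ValidationError(f"true_speed must be positive, got {self.true_speed}")


def barrier_speed(
    t_enter: float, t_exit: float, distance: float = BARRIER_DISTANCE_M
) -> float:
    """True mean speed over a timed course: ``distance / (t_exit - t_enter)``."""
    if distance <= 0:
        raise ValidationError("distance must be positive")
    if t_exit <= t_enter:
        raise ValidationError("t_exit must be after t_enter")
    return distance / (t_exit - t_enter)


def fit_calibration(
    samples: list[CalibrationSample], subject_id: str
) -> CalibrationModel:
    """Least-squares line ``speed = slope * cadence + intercept``.

    Requires at least two samples with at least two distinct cadence values;
    the RMSE of the fit over the training samples is stored on the model.
    Sample order does not affect the result.
    """
    if len(samples) < 2:
        raise ValidationError("calibration needs at least 2 samples")
    cad = np.array([s.cadence for s in samples])
    spd = np.array([s.true_speed for s in samples])
    if len(np.unique(cad)) < 2:
        raise ValidationError("calibration needs at least 2 distinct cadence values")
    fit = stats.linregress(cad, spd)
    pred = fit.slope * cad + fit.intercept
    rmse = float(np.sqrt(np.mean((pred - spd) ** 2)))
    return CalibrationModel(
        subject_id=subject_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_points=len(samples),
        rmse=rmse,
        fit_date=date.today().isoformat(),
        cadence_range=(float(cad.min()), float(cad.max())),
    )


def estimate_speed(model: CalibrationModel, cadence: float) -> float:
    """Predicted gait speed at a cadence, floored at zero.

    Physical speed cannot be negative, so predictions below zero (possible
    when extrapolating far below the calibrated range) are clipped to 0.
    """
    if not (np.isfinite(cadence) and cadence > 0):
        raise ValidationError(f"cadence must be positive, got {cadence}")
    return max(0.0, model.slope * cadence + model.intercept)


def in_calibrated_range(model: CalibrationModel, cadence: float) -> bool:
    """Whether a cadence lies inside the range seen during calibration."""
    if model.cadence_range is None:
        return True
    lo, hi = model.cadence_range
    return lo <= cadence <= hi
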