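"""Shared domain containers for foot-worn accelerometer gait analysis.

All quantities are SI internally: accelerations in m/s², times in seconds,
speeds in m/s, cadence in steps/second. A sample with index ``i`` in a
uniformly sampled record occurs at ``t0 + i / sample_rate_hz``; every event
time in the package is derived from a sample index through that rule, so the
index domain and the time domain can never drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Standard gravity, used to convert traces recorded in g to m/s².
STANDARD_GRAVITY = 9.80665

#: One stride (full gait cycle of one foot) equals two steps.
STEPS_PER_STRIDE = 2


class ValidationError(ValueError):
    """Raised when a domain invariant is violated at construction time."""


def _as_1d_float(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class AccelTrace:
    """Uniformly sampled 3-axis acceleration record.

    Parameters
    ----------
    sample_rate_hz
        Sampling frequency in Hz (the reference insole samples at 100 Hz).
    t0
        Time of the first sample, in seconds.
    ax, ay, az
        Per-axis acceleration in m/s², all of identical length ``N >= 1``.
    """

    sample_rate_hz: float
    t0: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ax", _as_1d_float(self.ax, "ax"))
        object.__setattr__(self, "ay", _as_1d_float(self.ay, "ay"))
        object.__setattr__(self, "az", _as_1d_float(self.az, "az"))
        validate_trace(self)

    def __len__(self) -> int:
        return len(self.ax)

    @property
    def times(self) -> np.ndarray:
        """Sample times ``t0 + i / sample_rate_hz``."""
        return self.t0 + np.arange(len(self)) / self.sample_rate_hz


def validate_trace(trace: AccelTrace) -> AccelTrace:
    """Return ``trace`` unchanged if all its invariants hold.

    Raises
    ------
    ValidationError
        On unequal axis lengths, non-positive sample rate or an empty trace.
    """
    if not np.isfinite(trace.sample_rate_hz) or trace.sample_rate_hz <= 0:
        raise ValidationError(
            f"sample_rate_hz must be positive, got {trace.sample_rate_hz}"
        )
    n = len(trace.ax)
    if n < 1:
        raise ValidationError("trace must contain at least one sample")
    if not (len(trace.ay) == n and len(trace.az) == n):
        raise ValidationError(
            "axis lengths differ: "
            f"ax={len(trace.ax)}, ay={len(trace.ay)}, az={len(trace.az)}"
        )
    return trace


@dataclass(frozen=True)
class ScalarSeries:
    """A uniformly sampled scalar series (magnitude, local mean, local variance).

    Shares the timing contract of :class:`AccelTrace`.
    """

    sample_rate_hz: float
    t0: float
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_1d_float(self.values, "values"))
        if not np.isfinite(self.sample_rate_hz) or self.sample_rate_hz <= 0:
            raise ValidationError(
                f"sample_rate_hz must be positive, got {self.sample_rate_hz}"
            )
        if len(self.values) < 1:
            raise ValidationError("series must contain at least one sample")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.sample_rate_hz


@dataclass(frozen=True)
class StrideEvent:
    """One detected stride: the rising and falling edge of a variance burst.

    ``rise_index``/``fall_index`` are sample indices into the analysed series;
    ``rise_time``/``fall_time`` are the corresponding times in seconds.
    """

    rise_index: int
    fall_index: int
    rise_time: float
    fall_time: float

    def __post_init__(self) -> None:
        if not (0 <= self.rise_index < self.fall_index):
            raise ValidationError(
                f"need 0 <= rise_index < fall_index, got {self.rise_index}, {self.fall_index}"
            )
        if not self.fall_time > self.rise_time:
            raise ValidationError("fall_time must exceed rise_time")


@dataclass(frozen=True)
class CadencePoint:
    """Instantaneous cadence anchored at the completion of the latest stride.

    Cadence is in steps/second and is only defined once four strides have been
    observed (a window spanning the last three inter-stride intervals).
    """

    time: float
    cadence: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.cadence) and self.cadence > 0):
            raise ValidationError(f"cadence must be positive, got {self.cadence}")


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted per-subject linear mapping from cadence to gait speed.

    ``speed = slope * cadence + intercept`` with slope in (m/s)/(steps/s).
    """

    subject_id: str
    slope: float
    intercept: float
    n_points: int
    rmse: float
    fit_date: str = ""
    cadence_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValidationError("a calibration needs at least 2 points")
        if not (np.isfinite(self.rmse) and self.rmse >= 0):
            raise ValidationError(f"rmse must be nonnegative, got {self.rmse}")
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValidationError("slope and intercept must be finite")


@dataclass
class ActivityPeriod:
    """One contiguous bout of walking and its summary quantities.

    ``mean_cadence``, ``mean_speed``, ``distance`` and ``energy_kcal`` are
    ``None`` until filled by the summary stage, and stay ``None`` for periods
    too short to yield a cadence (speed is never fabricated).
    """

    start_time: float
    end_time: float
    n_strides: int
    n_steps: int = field(default=0)
    mean_cadence: float | None = None
    mean_speed: float | None = None
    distance: float | None = None
    energy_kcal: float | None = None

    def __post_init__(self) -> None:
        if not self.end_time > self.start_time:
            raise ValidationError("end_time must exceed start_time")
        if self.n_strides < 1:
            raise ValidationError("a period must contain at least one stride")
        if self.n_steps == 0:
            self.n_steps = STEPS_PER_STRIDE * self.n_strides
        if self.n_steps != STEPS_PER_STRIDE * self.n_strides:
            raise ValidationError("n_steps must equal 2 x n_strides")

    @property
    def duration_s(self) -> float:
        return self.end_time - self.start_time


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth emitted by the gait simulator.

    ``true_stride_times`` are the exact heel-strike instants (strictly
    increasing); ``true_cadence`` equals ``2 / mean inter-stride interval``.
    """

    true_speed: float
    true_stride_times: np.ndarray
    true_cadence: float
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "true_stride_times",
            _as_1d_float(self.true_stride_times, "true_stride_times"),
        )
        t = self.true_stride_times
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValidationError("true_stride_times must be strictly increasing")

    @property
    def n_strides(self) -> int:
        return len(self.true_stride_times)
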