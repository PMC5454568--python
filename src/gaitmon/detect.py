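"""Variance-hysteresis stride detection and sliding-window cadence.

The detector runs in five stages on a 3-axis accelerometer record:

1. acceleration magnitude ``sqrt(ax² + ay² + az²)``;
2. centered local mean of the magnitude;
3. centered local variance of the magnitude — zero while the foot is still
   (the constant gravity component drops out), large during heel-strike
   bursts, which makes it the detection statistic;
4. dual-threshold (hysteresis) event detection on the variance: a crossing
   above ``t_rise`` opens a stride, a crossing below ``t_fall`` closes it,
   so dips or spikes between the two thresholds never chatter;
5. local cadence in steps/second over a sliding window of the last three
   strides (six steps, since one stride is two steps).

Local windows are centered and shrink at the series boundaries rather than
padding, so no fabricated samples influence the variance near the edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    AccelTrace,
    CadencePoint,
    ScalarSeries,
    StrideEvent,
    ValidationError,
    validate_trace,
)


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of the stride detector.

    Attributes
    ----------
    mean_window, var_window
        Odd window lengths in samples for the local mean and local variance
        (default 15 samples = 0.15 s at 100 Hz, shorter than the fastest
        plausible stance phase).
    t_rise, t_fall
        Hysteresis thresholds on the local variance, in (m/s²)²; ``t_rise``
        opens a stride, ``t_fall`` closes it, ``t_rise > t_fall > 0``.
    min_stride_s
        Debounce: a rising edge closer than this to the previous stride's
        rising edge is merged into it (fast walking keeps stride periods
        above ~0.8 s; half that guards against double-counted heel strikes).
    """

    mean_window: int = 15
    var_window: int = 15
    t_rise: float = 2.0
    t_fall: float = 0.5
    min_stride_s: float = 0.4

    def __post_init__(self) -> None:
        for name in ("mean_window", "var_window"):
            w = getattr(self, name)
            if w < 3 or w % 2 == 0:
                raise ValidationError(f"{name} must be an odd integer >= 3, got {w}")
        if not (self.t_rise > self.t_fall > 0):
            raise ValidationError(
                f"need t_rise > t_fall > 0, got t_rise={self.t_rise}, t_fall={self.t_fall}"
            )
        if self.min_stride_s <= 0:
            raise ValidationError("min_stride_s must be positive")


def magnitude(trace: AccelTrace) -> ScalarSeries:
    """Euclidean norm of the three acceleration axes, sample by sample."""
    validate_trace(trace)
    values = np.sqrt(trace.ax**2 + trace.ay**2 + trace.az**2)
    return ScalarSeries(trace.sample_rate_hz, trace.t0, values)


def _check_window(window: int, n: int) -> None:
    if window % 2 == 0:
        raise ValidationError(f"window must be odd, got {window}")
    if not 3 <= window <= n:
        raise ValidationError(f"window must satisfy 3 <= window <= {n}, got {window}")


def _windowed_sum(values: np.ndarray, half: int) -> tuple[np.ndarray, np.ndarray]:
    """Sum and count over centered windows clipped to the series bounds."""
    n = len(values)
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return csum[hi + 1] - csum[lo], (hi - lo + 1).astype(float)


def local_mean(series: ScalarSeries, window: int) -> ScalarSeries:
    """Centered moving average; windows shrink at the series edges."""
    _check_window(window, len(series))
    s, c = _windowed_sum(series.values, window // 2)
    return ScalarSeries(series.sample_rate_hz, series.t0, s / c)


def local_variance(
    series: ScalarSeries, window: int, mean_window: int | None = None
) -> ScalarSeries:
    """Centered moving variance about the local mean at each sample.

    ``out[i]`` is the mean over the centered ``window`` at ``i`` of
    ``(x - m(i))²``, where ``m`` is the local mean computed over
    ``mean_window`` (same as ``window`` when omitted). Adding any constant to
    the input leaves the output unchanged, which is what removes gravity from
    the magnitude.
    """
    _check_window(window, len(series))
    half = window // 2
    # shift by the first sample: algebraically a no-op (variance is shift
    # invariant) but keeps cancellation benign around a large gravity offset,
    # and makes a constant input yield exactly zero
    x = series.values - series.values[0]
    s1, c = _windowed_sum(x, half)
    s2, _ = _windowed_sum(x * x, half)
    if mean_window is None or mean_window == window:
        m = s1 / c
    else:
        shifted = ScalarSeries(series.sample_rate_hz, series.t0, x)
        m = local_mean(shifted, mean_window).values
    # E[(x - m_i)^2] over the window, with m_i held fixed across the window
    var = s2 / c - 2.0 * m * (s1 / c) + m * m
    # rounding can leave tiny negative values for near-constant windows
    np.maximum(var, 0.0, out=var)
    return ScalarSeries(series.sample_rate_hz, series.t0, var)


def detect_strides(
    var_series: ScalarSeries, config: DetectorConfig | None = None
) -> list[StrideEvent]:
    """Hysteresis thresholding of the local-variance series into strides.

    State machine: IDLE -> ACTIVE when the variance crosses above
    ``config.t_rise``; ACTIVE -> IDLE when it falls below ``config.t_fall``,
    emitting one :class:`StrideEvent` per rise/fall pair. A pair whose rising
    edge is closer than ``config.min_stride_s`` to the previous event's
    rising edge is suppressed (debounce). Quiet input yields an empty list.
    """
    config = config or DetectorConfig()
    v = var_series.values
    rate = var_series.sample_rate_hz
    t0 = var_series.t0

    # vectorised hysteresis: +1 above t_rise, -1 below t_fall, else carry the
    # previous non-neutral level forward
    marks = np.zeros(len(v), dtype=np.int8)
    marks[v > config.t_rise] = 1
    marks[v < config.t_fall] = -1
    nz = np.flatnonzero(marks)
    if len(nz) == 0:
        return []
    pos = np.zeros(len(v), dtype=np.intp)
    pos[nz] = nz
    np.maximum.accumulate(pos, out=pos)
    fill = marks[pos]
    fill[: nz[0]] = -1  # start IDLE until the first decisive crossing
    active = fill == 1

    edges = np.diff(active.astype(np.int8))
    rises = np.flatnonzero(edges == 1) + 1
    falls = np.flatnonzero(edges == -1) + 1
    if active[0]:
        rises = np.concatenate(([0], rises))
    # an unterminated final burst is dropped: its falling edge never occurred
    n_pairs = min(len(rises), len(falls))
    rises, falls = rises[:n_pairs], falls[:n_pairs]

    events: list[StrideEvent] = []
    last_rise_t = -np.inf
    for r, f in zip(rises, falls):
        rt = t0 + r / rate
        if rt - last_rise_t < config.min_stride_s:
            continue
        events.append(StrideEvent(int(r), int(f), rt, t0 + f / rate))
        last_rise_t = rt
    return events


def cadence_series(strides: list[StrideEvent]) -> list[CadencePoint]:
    """Sliding-window cadence over the last 3 strides (6 steps).

    For stride ``k >= 3`` (0-based), ``cadence = 6 / (rise_time[k] -
    rise_time[k-3])`` steps/second, anchored at ``rise_time[k]``. Fewer than
    four strides yield an empty list (the window needs three complete
    inter-stride intervals).
    """
    times = np.array([s.rise_time for s in strides], dtype=float)
    if len(times) >= 2 and not np.all(np.diff(times) > 0):
        raise ValidationError("stride times must be strictly increasing")
    points: list[CadencePoint] = []
    for k in range(3, len(times)):
        span = times[k] - times[k - 3]
        points.append(CadencePoint(time=float(times[k]), cadence=6.0 / span))
    return points


def run_detector(
    trace: AccelTrace, config: DetectorConfig | None = None
) -> tuple[list[StrideEvent], list[CadencePoint]]:
    """Full pipeline: magnitude -> local mean/variance -> strides -> cadence."""
    config = config or DetectorConfig()
    mag = magnitude(trace)
    var = local_variance(mag, config.var_window, mean_window=config.mean_window)
    strides = detect_strides(var, config)
    return strides, cadence_series(strides)
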