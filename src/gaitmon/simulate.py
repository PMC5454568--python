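"""Synthetic treadmill-walking accelerometer traces with known ground truth.

No raw recordings of the original living-laboratory sessions exist, so this
module emulates them: walking at a fixed belt speed produces a periodic train
of heel-strike impact bursts riding on a constant gravity offset, a gentler
swing-phase oscillation, and sensor noise. The generator is the source of
ground truth for validation — it records the exact heel-strike instants it
synthesised, so stride counts and cadence can be scored against the truth.

The waveform is deliberately phenomenological: a Gaussian-envelope impact
transient at each heel strike plus a stride-frequency sinusoid for the swing
phase. The downstream detector only consumes variance bursts, so burst
timing and amplitude are what matter, not biomechanical detail.

The subject's gait is governed by a linear cadence-speed relation
``cadence = cadence_intercept + cadence_slope * speed`` — the individual
relationship that calibration later has to recover from the outside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import AccelTrace, STANDARD_GRAVITY, SimulationTruth, ValidationError

#: The five fixed treadmill belt speeds of the validation protocol, m/s.
PROTOCOL_SPEEDS = (0.5, 0.75, 1.0, 1.25, 1.5)


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one simulated walker.

    ``cadence_slope``/``cadence_intercept`` define the subject's true
    cadence-speed line (steps/s per m/s and steps/s). The defaults give
    1.9 steps/s at 1.0 m/s, in the normal walking range. ``impact_amplitude``
    scales the heel-strike transient; ``noise_sd`` is the per-axis sensor
    noise; ``stride_jitter_cv`` is the coefficient of variation of the
    stride period (~1% for a stable gait).
    """

    subject_id: str = "sim-subject"
    body_mass: float = 70.0
    cadence_slope: float = 1.2
    cadence_intercept: float = 0.7
    impact_amplitude: float = 25.0
    noise_sd: float = 0.3
    stride_jitter_cv: float = 0.01

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValidationError("body_mass must be positive")
        if self.cadence_slope <= 0:
            raise ValidationError("cadence_slope must be positive (cadence rises with speed)")
        if self.impact_amplitude <= self.noise_sd:
            raise ValidationError("impact_amplitude must exceed noise_sd")
        if self.stride_jitter_cv < 0:
            raise ValidationError("stride_jitter_cv must be nonnegative")

    def true_cadence(self, speed: float) -> float:
        """Ground-truth cadence (steps/s) at a given speed (m/s)."""
        return self.cadence_intercept + self.cadence_slope * speed


@dataclass(frozen=True)
class ProtocolSpec:
    """A treadmill validation protocol: fixed speeds, fixed stride counts."""

    speeds: tuple[float, ...] = PROTOCOL_SPEEDS
    strides_per_speed: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.speeds):
            raise ValidationError("all protocol speeds must be positive")
        if self.strides_per_speed < 1:
            raise ValidationError("strides_per_speed must be >= 1")


def generate_walk(
    speed: float,
    n_strides: int,
    profile: SubjectProfile | None = None,
    seed: int = 0,
    sample_rate_hz: float = 100.0,
) -> tuple[AccelTrace, SimulationTruth]:
    """Synthesise one constant-speed walk of ``n_strides`` strides.

    The stride period is ``2 / cadence`` with lognormal multiplicative jitter
    of coefficient of variation ``profile.stride_jitter_cv``. Each stride
    contributes a short high-amplitude impact burst at heel strike and a
    lower-amplitude swing sinusoid; gravity sits on the z axis and zero-mean
    Gaussian noise of ``profile.noise_sd`` is added per axis. Identical
    arguments (including ``seed``) give bit-identical output.

    Returns the trace and a :class:`SimulationTruth` carrying the exact
    heel-strike instants.
    """
    profile = profile or SubjectProfile()
    if speed <= 0:
        raise ValidationError("speed must be positive")
    if n_strides < 1:
        raise ValidationError("n_strides must be >= 1")

    rng = np.random.default_rng(seed)
    cadence = profile.true_cadence(speed)
    period = 2.0 / cadence  # one stride = two steps

    # lognormal jitter with the requested CV, unit mean
    cv = profile.stride_jitter_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv * cv))
        factors = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n_strides)
    else:
        factors = np.ones(n_strides)
    intervals = period * factors
    lead_in = 1.0
    stride_times = lead_in + np.concatenate(([0.0], np.cumsum(intervals[:-1])))

    duration = stride_times[-1] + period + lead_in
    n = int(np.ceil(duration * sample_rate_hz)) + 1
    t = np.arange(n) / sample_rate_hz

    # heel-strike impacts: Gaussian envelope times a fast oscillation
    impact_sigma = 0.025  # s, burst half-width
    impact_freq = 18.0  # Hz, dominant shock frequency
    vertical = np.zeros(n)
    fore_aft = np.zeros(n)
    for k, ts in enumerate(stride_times):
        lo = max(0, int((ts - 5 * impact_sigma) * sample_rate_hz))
        hi = min(n, int((ts + 5 * impact_sigma) * sample_rate_hz) + 1)
        dt = t[lo:hi] - ts
        env = np.exp(-0.5 * (dt / impact_sigma) ** 2)
        burst = profile.impact_amplitude * env * np.cos(2 * np.pi * impact_freq * dt)
        vertical[lo:hi] += burst
        fore_aft[lo:hi] += 0.4 * burst

    # swing-phase oscillation at stride frequency, well below the thresholds
    swing = 0.6 * np.sin(2 * np.pi * (t - lead_in) / period)

    ax = fore_aft + swing + rng.normal(0.0, profile.noise_sd, n)
    ay = 0.3 * swing + rng.normal(0.0, profile.noise_sd, n)
    az = STANDARD_GRAVITY + vertical + rng.normal(0.0, profile.noise_sd, n)

    trace = AccelTrace(sample_rate_hz, 0.0, ax, ay, az)
    true_cadence = (
        2.0 / float(np.mean(intervals)) if n_strides > 1 else cadence
    )
    truth = SimulationTruth(
        true_speed=speed,
        true_stride_times=stride_times,
        true_cadence=true_cadence,
        seed=seed,
    )
    return trace, truth


def generate_quiet(
    duration_s: float,
    profile: SubjectProfile | None = None,
    seed: int = 0,
    sample_rate_hz: float = 100.0,
) -> AccelTrace:
    """Standing/sitting negative control: gravity offset plus noise only."""
    profile = profile or SubjectProfile()
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n = int(np.ceil(duration_s * sample_rate_hz)) + 1
    ax = rng.normal(0.0, profile.noise_sd, n)
    ay = rng.normal(0.0, profile.noise_sd, n)
    az = STANDARD_GRAVITY + rng.normal(0.0, profile.noise_sd, n)
    return AccelTrace(sample_rate_hz, 0.0, ax, ay, az)


def generate_protocol(
    protocol: ProtocolSpec | None = None,
    profile: SubjectProfile | None = None,
    sample_rate_hz: float = 100.0,
) -> list[tuple[float, AccelTrace, SimulationTruth]]:
    """One walk segment per protocol speed, seeded deterministically.

    Segment ``i`` uses seed ``protocol.seed + i``, so protocols are
    reproducible yet segments are mutually distinct.
    """
    protocol = protocol or ProtocolSpec()
    profile = profile or SubjectProfile()
    segments = []
    for i, speed in enumerate(protocol.speeds):
        trace, truth = generate_walk(
            speed,
            protocol.strides_per_speed,
            profile,
            seed=protocol.seed + i,
            sample_rate_hz=sample_rate_hz,
        )
        segments.append((speed, trace, truth))
    return segments


def error_table(
    speeds: list[float],
    truth_counts: list[int],
    detected_counts: list[int],
) -> pd.DataFrame:
    """Per-speed stride-count errors plus a total row.

    Columns mirror the treadmill validation report: true stride count,
    detected stride count and ``|detected - true| / true x 100`` percent
    error, with a final ``total`` row aggregated over all speeds.
    """
    if not (len(speeds) == len(truth_counts) == len(detected_counts)):
        raise ValidationError("speeds, truth_counts and detected_counts must align")
    if any(c <= 0 for c in truth_counts):
        raise ValidationError("truth counts must be positive")
    rows = []
    for speed, true_n, det_n in zip(speeds, truth_counts, detected_counts):
        rows.append(
            {
                "speed_mps": speed,
                "true_strides": true_n,
                "detected_strides": det_n,
                "error_pct": abs(det_n - true_n) / true_n * 100.0,
            }
        )
    total_true = sum(truth_counts)
    total_det = sum(detected_counts)
    rows.append(
        {
            "speed_mps": "total",
            "true_strides": total_true,
            "detected_strides": total_det,
            "error_pct": abs(total_det - total_true) / total_true * 100.0,
        }
    )
    return pd.DataFrame(rows)
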