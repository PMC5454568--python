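"""Activity-period segmentation and daily summaries.

Free-living monitoring reports, per walking bout: duration, step count,
average speed, distance and an indirect energy estimate. Bouts are found at
the stride level: consecutive strides separated by no more than a quiet-gap
threshold belong to the same activity period, and periods with too few
strides to fill the cadence window are kept for step counting but never
assigned a speed or distance.

Energy is the standard MET-based indirect estimate,
``kcal = MET x body_mass_kg x duration_hours``, with a configurable walking
MET (default 3.5). It is a placeholder-grade estimate: it uses only the
quantities the insole measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .calibration import estimate_speed
from .types import (
    ActivityPeriod,
    CadencePoint,
    CalibrationModel,
    StrideEvent,
    ValidationError,
)


@dataclass(frozen=True)
class SummaryConfig:
    """Segmentation and energy knobs for activity summaries.

    ``activity_gap_s``: maximum quiet gap (between consecutive stride rising
    edges) inside one period, default 10 s. ``min_period_strides``: periods
    with fewer strides are discarded, default 4 — the cadence warm-up, below
    which a period cannot yield a speed. ``met_walking``: MET value used in
    the indirect energy estimate.
    """

    activity_gap_s: float = 10.0
    min_period_strides: int = 4
    met_walking: float = 3.5

    def __post_init__(self) -> None:
        if self.activity_gap_s <= 0:
            raise ValidationError("activity_gap_s must be positive")
        if self.min_period_strides < 1:
            raise ValidationError("min_period_strides must be >= 1")
        if self.met_walking <= 0:
            raise ValidationError("met_walking must be positive")


def segment_activity(
    strides: list[StrideEvent], config: SummaryConfig | None = None
) -> list[ActivityPeriod]:
    """Group time-ordered strides into activity periods (geometry only).

    Consecutive strides whose rising edges are separated by at most
    ``config.activity_gap_s`` share a period; periods with fewer than
    ``config.min_period_strides`` strides are dropped. Period bounds are the
    first stride's rise time and the last stride's fall time.
    """
    config = config or SummaryConfig()
    if not strides:
        return []
    groups: list[list[StrideEvent]] = [[strides[0]]]
    for prev, cur in zip(strides, strides[1:]):
        if cur.rise_time - prev.rise_time <= config.activity_gap_s:
            groups[-1].append(cur)
        else:
            groups.append([cur])
    periods = []
    for g in groups:
        if len(g) < config.min_period_strides:
            continue
        periods.append(
            ActivityPeriod(
                start_time=g[0].rise_time,
                end_time=g[-1].fall_time,
                n_strides=len(g),
            )
        )
    return periods


def summarize_period(
    period: ActivityPeriod,
    cadences: list[CadencePoint],
    model: CalibrationModel,
    config: SummaryConfig | None = None,
    body_mass: float = 70.0,
) -> ActivityPeriod:
    """Fill a period's speed, distance and energy from its cadence points.

    ``mean_speed`` is the calibrated prediction at the mean in-period
    cadence; ``distance = mean_speed x duration``; energy uses the MET
    formula. A period with no in-period cadence points (fewer than four
    strides) keeps its step count but leaves speed, distance and energy
    unset rather than fabricating them.
    """
    config = config or SummaryConfig()
    in_period = [
        c.cadence for c in cadences if period.start_time <= c.time <= period.end_time
    ]
    filled = ActivityPeriod(
        start_time=period.start_time,
        end_time=period.end_time,
        n_strides=period.n_strides,
    )
    if not in_period:
        return filled
    filled.mean_cadence = float(np.mean(in_period))
    filled.mean_speed = estimate_speed(model, filled.mean_cadence)
    filled.distance = filled.mean_speed * filled.duration_s
    hours = filled.duration_s / 3600.0
    filled.energy_kcal = config.met_walking * body_mass * hours
    return filled


def daily_report(periods: list[ActivityPeriod]) -> dict[str, Any]:
    """Aggregate per-period rows into daily totals.

    Totals are exact sums over the per-period values; periods without a
    speed contribute steps and minutes but no distance or energy.
    """
    rows = []
    for p in periods:
        rows.append(
            {
                "start_time_s": p.start_time,
                "end_time_s": p.end_time,
                "duration_min": p.duration_s / 60.0,
                "n_strides": p.n_strides,
                "n_steps": p.n_steps,
                "mean_cadence_sps": p.mean_cadence,
                "mean_speed_mps": p.mean_speed,
                "distance_m": p.distance,
                "energy_kcal": p.energy_kcal,
            }
        )
    return {
        "totals": {
            "active_minutes": sum(r["duration_min"] for r in rows),
            "n_steps": sum(r["n_steps"] for r in rows),
            "distance_m": sum(r["distance_m"] or 0.0 for r in rows),
            "energy_kcal": sum(r["energy_kcal"] or 0.0 for r in rows),
            "n_periods": len(rows),
        },
        "periods": rows,
    }
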