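"""Stride-detection pipeline: oracles, hysteresis contract, cadence formula.

The moving-window operations are checked against brute-force loops over all
centered windows (the independent oracle), and the hysteresis detector
against pulse trains whose event counts are known by construction.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from gaitmon import (
    AccelTrace,
    DetectorConfig,
    StrideEvent,
    ValidationError,
    cadence_series,
    detect_strides,
    local_mean,
    local_variance,
    magnitude,
    run_detector,
)
from conftest import series


# ---------------------------------------------------------------- oracles


def brute_local_mean(x, window):
    half = window // 2
    out = np.empty_like(x, dtype=float)
    for i in range(len(x)):
        w = x[max(0, i - half) : min(len(x), i + half + 1)]
        out[i] = np.mean(w)
    return out


def brute_local_variance(x, window):
    half = window // 2
    m = brute_local_mean(x, window)
    out = np.empty_like(x, dtype=float)
    for i in range(len(x)):
        w = x[max(0, i - half) : min(len(x), i + half + 1)]
        out[i] = np.mean((w - m[i]) ** 2)
    return out


# -------------------------------------------------------------- magnitude


def test_magnitude_basic_cases():
    n = 4
    zero = AccelTrace(100.0, 0.0, np.zeros(n), np.zeros(n), np.zeros(n))
    assert np.all(magnitude(zero).values == 0.0)

    grav = AccelTrace(100.0, 0.0, np.zeros(n), np.zeros(n), np.full(n, 9.81))
    assert magnitude(grav).values == pytest.approx(np.full(n, 9.81))

    tri = AccelTrace(100.0, 0.0, np.array([3.0]), np.array([4.0]), np.array([0.0]))
    assert magnitude(tri).values[0] == pytest.approx(5.0)


def test_magnitude_rotation_invariant(rng):
    """The norm of the axis triple is preserved under any rigid rotation."""
    n = 200
    a = rng.normal(0, 3, (3, n))
    rot = Rotation.random(random_state=7).as_matrix()
    b = rot @ a
    m1 = magnitude(AccelTrace(100.0, 0.0, *a)).values
    m2 = magnitude(AccelTrace(100.0, 0.0, *b)).values
    assert m1 == pytest.approx(m2, rel=1e-12)


# ---------------------------------------------------- local mean/variance


def test_local_mean_hand_computed_edges():
    # centered window shrinking at the boundaries
    out = local_mean(series([0, 0, 3, 0, 0]), 3)
    assert out.values == pytest.approx([0, 1, 1, 1, 0])


def test_local_mean_of_constant_is_constant():
    out = local_mean(series(np.full(50, 7.25)), 9)
    assert out.values == pytest.approx(np.full(50, 7.25), rel=1e-12)


@pytest.mark.parametrize("window", [3, 5, 15])
def test_windowed_ops_match_brute_force(rng, window):
    x = rng.normal(9.8, 2.0, 300)
    s = series(x)
    assert local_mean(s, window).values == pytest.approx(
        brute_local_mean(x, window), rel=1e-9
    )
    assert local_variance(s, window).values == pytest.approx(
        brute_local_variance(x, window), rel=1e-9, abs=1e-12
    )


def test_local_variance_of_constant_is_exactly_zero():
    out = local_variance(series(np.full(100, 9.80665)), 15)
    assert np.all(out.values == 0.0)


def test_local_variance_shift_invariant(rng):
    x = rng.normal(0, 1, 200)
    v0 = local_variance(series(x), 11).values
    v1 = local_variance(series(x + 9.80665), 11).values
    assert v1 == pytest.approx(v0, abs=1e-10)


@pytest.mark.parametrize("window,err", [(4, "odd"), (999, "window"), (1, "window")])
def test_window_validation(window, err):
    with pytest.raises(ValidationError, match=err):
        local_mean(series(np.zeros(50)), window)


@settings(max_examples=50, deadline=None)
@given(
    data=st.lists(st.floats(-50, 50), min_size=7, max_size=60),
    window=st.sampled_from([3, 5, 7]),
)
def test_windowed_ops_property(data, window):
    """Oracle equivalence and nonnegativity hold on arbitrary finite input."""
    x = np.asarray(data)
    s = series(x)
    assert local_mean(s, window).values == pytest.approx(
        brute_local_mean(x, window), rel=1e-9, abs=1e-9
    )
    v = local_variance(s, window).values
    assert np.all(v >= 0)
    assert v == pytest.approx(brute_local_variance(x, window), rel=1e-9, abs=1e-7)


# --------------------------------------------------------------- strides


def pulse_train(n_pulses, high=3.0, pulse_len=20, gap=80, rate=100.0):
    v = np.zeros(100 + n_pulses * (pulse_len + gap))
    for k in range(n_pulses):
        start = 50 + k * (pulse_len + gap)
        v[start : start + pulse_len] = high
    return series(v, rate=rate)


def test_quiet_variance_yields_no_strides():
    assert detect_strides(series(np.full(1000, 0.1)), DetectorConfig()) == []


def test_pulse_train_count_exact():
    events = detect_strides(pulse_train(10), DetectorConfig())
    assert len(events) == 10
    times = [e.rise_time for e in events]
    assert all(b > a for a, b in zip(times, times[1:]))
    assert all(e.fall_index > e.rise_index for e in events)
    # disjoint: each event falls before the next rises
    assert all(b.rise_index > a.fall_index for a, b in zip(events, events[1:]))


def test_hysteresis_dip_does_not_split_stride():
    """A dip between t_fall and t_rise inside a burst is not a new stride."""
    v = np.zeros(400)
    v[100:120] = 3.0
    v[120:140] = 1.0  # between t_fall=0.5 and t_rise=2.0
    v[140:160] = 3.0
    events = detect_strides(series(v), DetectorConfig())
    assert len(events) == 1
    assert events[0].fall_index >= 160


def test_hysteresis_subthreshold_spike_creates_nothing():
    """A spike between t_fall and t_rise from idle never opens a stride."""
    v = np.zeros(400)
    v[200:220] = 1.0
    assert detect_strides(series(v), DetectorConfig()) == []


def test_debounce_suppresses_close_pairs():
    # two pulses 0.2 s apart: second suppressed with min_stride_s=0.4
    v = np.zeros(400)
    v[100:105] = 3.0
    v[120:125] = 3.0
    events = detect_strides(series(v), DetectorConfig())
    assert len(events) == 1


def test_active_at_trace_start_and_unterminated_end():
    # starts above t_rise -> counts from sample 0; final open burst dropped
    v = np.zeros(300)
    v[:20] = 3.0
    v[280:] = 3.0
    events = detect_strides(series(v), DetectorConfig())
    assert len(events) == 1
    assert events[0].rise_index == 0


# --------------------------------------------------------------- cadence


def strides_at(times):
    return [StrideEvent(int(t * 100), int(t * 100) + 5, t, t + 0.05) for t in times]


def test_cadence_periodic_strides():
    # stride period 1 s -> 2 steps/s, emitted at the 4th stride
    pts = cadence_series(strides_at([0.0, 1.0, 2.0, 3.0]))
    assert len(pts) == 1
    assert pts[0].time == pytest.approx(3.0)
    assert pts[0].cadence == pytest.approx(2.0)


def test_cadence_needs_four_strides():
    assert cadence_series(strides_at([0.0, 1.0, 2.0])) == []
    assert cadence_series([]) == []


def test_cadence_irregular_times():
    pts = cadence_series(strides_at([0.0, 0.9, 2.0, 3.1]))
    assert pts[0].cadence == pytest.approx(6.0 / 3.1)


def test_cadence_rejects_non_monotone():
    with pytest.raises(ValidationError):
        cadence_series(strides_at([0.0, 2.0, 1.0, 3.0]))


@settings(max_examples=30, deadline=None)
@given(period=st.floats(0.5, 2.0), n=st.integers(4, 20))
def test_cadence_exact_on_periodic_gait(period, n):
    """Perfectly periodic strides of period T give cadence 2/T exactly."""
    pts = cadence_series(strides_at([k * period for k in range(n)]))
    assert len(pts) == n - 3
    for p in pts:
        assert p.cadence == pytest.approx(2.0 / period, rel=1e-9)


# ------------------------------------------------------------- pipeline


def test_run_detector_quiet_trace(quiet_trace):
    strides, cadences = run_detector(quiet_trace)
    assert strides == [] and cadences == []


def test_run_detector_recovers_simulated_strides(profile):
    from gaitmon import generate_walk

    trace, truth = generate_walk(1.0, 100, profile, seed=42)
    strides, cadences = run_detector(trace)
    assert abs(len(strides) - truth.n_strides) <= 1  # <=1% of 100
    assert all(np.isfinite(c.cadence) and c.cadence > 0 for c in cadences)
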