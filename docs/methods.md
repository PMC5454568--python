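# Methods

## Detection model

The detector treats the windowed variance of the acceleration magnitude as
the activity statistic. The magnitude makes the statistic independent of
sensor orientation; the windowed variance removes any constant offset —
including gravity — exactly, so a still foot scores zero while a heel strike
produces a sharp burst. Strides are extracted from the variance series by a
two-threshold (hysteresis) state machine: IDLE→ACTIVE when the variance
crosses above `t_rise`, ACTIVE→IDLE when it falls below `t_fall`. Because the
two thresholds differ, excursions in the band between them can neither split
a burst into two strides nor promote noise into one. Cadence is computed per
completed stride over the last three inter-stride intervals (six steps):
`c_k = 6 / (t_k − t_{k−3})` steps/s, anchored at the rising edge of stride
`k`; nothing is emitted before the fourth stride, since the window needs
three full intervals.

Assumptions: one stride produces exactly one variance burst clearing
`t_rise`, and the inter-burst floor stays below `t_fall`. Gait that violates
this — shuffling with very weak heel strikes, or foot tremor between steps —
degrades gracefully into missed or debounced events rather than failures.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `mean_window`, `var_window` | 15 | samples | centered windows (0.15 s at 100 Hz); shorter than the fastest plausible stance phase so bursts are not smeared together |
| `t_rise` | 2.0 | (m/s²)² | opens a stride; well above the sensor-noise variance floor (~0.1 for 0.3 m/s² noise), well below heel-strike burst variance (~100) |
| `t_fall` | 0.5 | (m/s²)² | closes a stride; above the noise floor, below the burst tail |
| `min_stride_s` | 0.4 | s | debounce; fast walking keeps stride periods ≥ ~0.8 s, half that guards against double-counting one heel strike |
| `activity_gap_s` | 10 | s | maximum quiet gap inside one activity bout |
| `min_period_strides` | 4 | strides | the cadence warm-up; shorter bouts cannot yield a speed |
| `met_walking` | 3.5 | — | MET constant for the indirect energy estimate |

No window lengths or threshold values are prescribed by the measurement
principle itself; the defaults above are the package's operating point, all
exposed in the config file and as CLI flags. Tests exercise the hysteresis
contract, not the particular default values.

## Numerical choices

Centered windows shrink at the series boundaries instead of padding, so no
fabricated samples influence edge variance. The moving mean and variance are
computed by cumulative sums; the variance computation first subtracts the
first sample of the series — algebraically a no-op (variance is shift
invariant) — which keeps cancellation benign around the ~9.8 m/s² gravity
offset and makes a constant input yield exactly zero. Tiny negative variance
values from rounding are clipped to zero. A burst still open at the end of a
trace has no falling edge and is dropped. A trace that starts above `t_rise`
opens a stride at sample 0. Debouncing compares rising-edge times: a pair
whose rise is within `min_stride_s` of the previous kept event is merged.
When `mean_window ≠ var_window`, the variance at sample `i` is the
`var_window`-mean of squared deviations from the `mean_window` local mean
held fixed at `i`.

Whether the embedded original used centered or trailing (causal) windows is
unknown; centered windows were chosen here for symmetry of edge behaviour,
and event times come from the threshold crossings themselves, so the choice
shifts detections by at most half a window.

## Calibration

Speed is predicted from cadence by an ordinary least-squares line
(`scipy.stats.linregress`), the minimal model consistent with the strong
linear cadence–speed correlation of normal walking; the module contract
permits swapping in a monotone spline if frail gait turns out nonlinear.
Ground-truth speeds come from a timed course (`barrier_speed`, default 4 m).
Predictions are floored at 0 m/s, and the model stores its fit date, sample
count, RMSE and calibrated cadence range so out-of-range use can be flagged
(`in_calibrated_range`). Recalibration is simply refitting with new samples.

## Synthetic data

The simulator emulates fixed-speed treadmill walking: a subject's gait is
governed by a linear cadence–speed relation (default `cadence = 0.7 +
1.2 × speed` steps/s, giving 1.9 steps/s at 1.0 m/s — normal-walking range),
stride periods carry lognormal multiplicative jitter with 1% coefficient of
variation (a stable gait), and each heel strike contributes a
Gaussian-envelope impact transient (default 25 m/s² peak, 25 ms half-width,
18 Hz carrier) on the vertical and fore–aft axes plus a 0.6 m/s²
stride-frequency swing sinusoid, riding on standard gravity and 0.3 m/s²
per-axis Gaussian noise. The generator records the exact heel-strike
instants it synthesised, so detection can be scored against truth. All
generators are pure functions of their arguments and seed; protocol segment
`i` uses `seed + i`.

What it does **not** model: biomechanical waveform detail beyond burst
timing/amplitude, sensor quantization and range clipping, pathological or
frail gait (weak heel strikes, shuffling), turns, stairs, and non-gait foot
motion. Passing tests therefore demonstrate that the algorithm correctly
implements the detection principle and meets its accuracy bounds *under the
stated signal model* — not that it would meet them on recordings from frail
walkers, which is precisely the open clinical question.

## Problem sizes

The validation suite uses the treadmill protocol at its stated size — 5
speeds (0.5–1.5 m/s in 0.25 steps) × 100 strides — repeated for three
simulated subjects (1500 strides) for stride counting, 200-stride walks per
speed for cadence stability, and a 5-speed training protocol plus four
held-out 100-stride walks (0.6, 0.9, 1.1, 1.4 m/s) for speed accuracy. The
whole experiment runs in seconds.

## Energy estimate

Walking energy is the standard MET-based indirect estimate
`kcal = MET × body_mass_kg × duration_h` with MET 3.5 by default. It uses
only quantities the insole measures and is placeholder-grade: it ignores
speed and grade dependence of walking cost. Periods without a cadence (fewer
than four strides) keep their step counts but are excluded from speed,
distance and energy — speed is never fabricated.

## Known limitations

- Detection assumes one variance burst per stride; double-support scuffs or
  very soft heel strikes can merge or miss events.
- The cadence–speed line is assumed stable between calibrations; drift is
  handled by refitting, not modelled.
- The activity gate operates at stride level (a bout is a run of detected
  strides), not at raw-variance level; sub-stride activity is invisible.
- The simulator's realism floor (bursts clear `t_rise`, floor below
  `t_fall`) is itself asserted by tests, making the end-to-end accuracy
  claims honest about their scope.
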