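# Methods

`reachrc` implements a reverse-correlation (step-triggered averaging)
analysis of continuous visuomotor feedback corrections in a fast
interception task, together with a synthetic-trial simulator that gives
every stage of the analysis a known ground truth.

## The task and the perturbation

A participant slides a finger (represented on screen by a cursor) from a
start point through the path of a target that appears 30 cm to the left and
20 cm beyond the start and moves rightward at 50 cm/s.  On every display
frame (60 Hz) a lateral step of fixed amplitude (2.5 mm) and random sign is
added either to the target's position or to the cursor offset (the
displacement between displayed cursor and true finger position); the steps
accumulate as a random walk.  One 2.5 mm step per frame is equivalent to a
jitter velocity of 15 cm/s.  Finger position is sampled at 500 Hz.  A trial
counts as a hit if the interpolated cursor centre ever falls within the
target disc (radius 13.5 mm); both trajectories are treated as piecewise
linear and each segment's minimum distance is found in closed form, so a hit
that exists only between samples is detected.

## Reverse correlation

Because each frame's step direction is an independent fair coin, the
response to the step at one frame can be isolated by splitting trials on
that step's direction and differencing the group-mean lateral accelerations:
the steps at every other frame are equally often left and right in both
groups and cancel in expectation.  Conditioning on a step separates the
group-mean perturbation trajectories by exactly twice the step amplitude
(5 mm) from that frame onward — this is the quantity `scripts/acceptance.py`
recomputes.

Time is anchored to the *end of the movement*: the linearly interpolated
moment the finger crosses the target's path, or, if it stops less than 2 cm
short of the path, the moment of maximal distance from the start (trials
stopping further short are excluded outright; annotation is total — every
trial is either annotated or explicitly excluded).  Display frames are
indexed backwards from the last frame at or before the end (which therefore
lies 0–17 ms before it), and only steps strictly more than 100 ms before the
end are analysed, since earlier responses are physiologically impossible.
Validity is decided on actual times, not on the frame index, because the
synchronisation offset shifts frame times relative to the end.

Lateral acceleration is estimated by fitting a second-order polynomial to
the finger positions within a 40 ms window centred on the moment of interest
and taking twice the quadratic coefficient.  On the regular 500 Hz grid this
is exactly the 21-point Savitzky–Golay second-derivative filter; for centre
times off the grid (frame times at 60 Hz never coincide with 500 Hz
samples) the same least-squares fit is applied to the 20 samples inside the
window.  Windows that are not fully contained in the record yield no value:
the point is dropped, never padded, because padding would bias accelerations
near the movement end, exactly where responses matter.  The estimator is
exact on polynomials up to the fit order and linear in the input.

Response curves run from the step for 250 ms in steps of one sample
interval, truncated at each trial's own end of movement (a trial drops out
of any lag its record cannot support; the curve stops where trials run
out).  The difference is signed compensatory-positive: acceleration in the
direction of a target step, or opposite to a cursor step, is positive.
Accelerations are estimated per trial and then averaged (not estimated on
averaged positions): the two orders agree for this linear estimator only
when every trial contributes to every lag, which truncation breaks.
Curves are computed per session and averaged unweighted across sessions.

## Vigour read-outs and the origin-line construction

Curves are reduced to values at fixed lags after the step (160, 170, 180 ms
by default, where responses in both channels are well developed).  Plotting
the cursor response against the target response across step times tests
whether the two channels' vigour grows in the same way as the movement nears
its end: if so, the points lie on a straight line through the origin whose
slope is the relative cursor weight.  The slope is the least-squares
through-origin slope Σtc/Σt²; the bend is quantified as the quadratic
coefficient b of the through-origin fit c ≈ a·t + b·t², with a seeded
percentile bootstrap (2,000 replicates by default) over step-time pairs.
A positive b with an interval excluding zero means the cursor response grows
disproportionately late.

Pairs are dropped pairwise where either curve is undefined at the lag.  In
addition, step times whose curves draw on fewer than half of the maximally
available trials at that lag are excluded (`min_support`, default 0.5): for
steps delivered much longer before the end than the typical movement
duration, only the few longest trials contribute, and conditional means over
a handful of trials are statistically meaningless and corrupt the fit.  This
support filter is a degrees-of-freedom requirement, not a tunable analysis
choice.

## The simulator

The analysis needs data with known structure; the generative
law is an invented, deliberately simple linear-superposition controller
(no biomechanics, no eye movements):

- **Baseline reach**: a minimum-jerk trajectory from the start point to a
  point 35 mm beyond the target's path, scaled so the finger crosses the
  path exactly where the unperturbed target will then be, at the planned
  crossing time (nominal 0.58 s, SD 0.045 s across trials).  Aiming beyond
  the path makes the finger cross it at realistic speed instead of stopping
  on it.
- **Corrective responses**: each frame's step injects, after a 110 ms
  latency, a lateral acceleration `±A · gain(t_remaining) · h(t − t_step −
  latency)`, where `h` is a unit-integral gamma density (mode 100 ms after
  onset, SD 50 ms) and the sign follows the step for target jitter and
  opposes it (scaled by `cursor_weight`, default 0.6) for cursor jitter —
  compensatory in both cases.  The default gain is `0.7 / max(t_remaining,
  0.1 s)` per second: corrections supply 70% of the velocity change that
  full compensation within the remaining time would require, so response
  vigour grows as the end approaches.  An optional independent cursor-gain
  schedule simulates the alternative hypothesis that reliance on visual hand
  information rises disproportionately late.
- **Noise**: white acceleration noise on both axes, SD 950 mm/s² per 500 Hz
  sample.  This value was calibrated so that default sessions land near a
  70% hit rate (measured 0.70 over 2,000 trials); together with the planned
  duration variability it gives end-of-movement times of roughly 585 ± 60 ms.
- **Sessions**: target- and cursor-jitter trials balanced to within one and
  interleaved in seeded random order.  One master seed derives per-trial
  seeds deterministically, so identical seeds give byte-identical sessions.

Because the law is linear in the steps, the analysis has a closed-form
oracle: the expected curve is `2 · A · gain(t_before_end) · h(lag −
latency)` for target steps and `cursor_weight` times that for cursor steps,
and the origin-line slope equals `cursor_weight`.

### What the simulator does not emulate

Real reaches have structured (non-white) motor variability, trial-to-trial
strategy changes, reaction-time variability at movement start, biomechanical
filtering of the commanded accelerations, and gaze-dependent sensory noise.
Passing parameter-recovery tests therefore shows that the *analysis
pipeline* is correct and unbiased under a known generative law of the right
general shape — not that the law describes human controllers.

## Finite-trial noise and problem sizes

A property of reverse correlation worth emphasising: even with zero motor
noise the estimated kernels fluctuate, because in any finite sample the
*other* steps only cancel approximately (∝ 1/√n_trials).  With ~4,400
trials per condition the per-point kernel SE at the read-out lags is
~13–17 mm/s².  Noise in the target-response values also attenuates the
origin slope (classical errors-in-variables): the recovery tests therefore
use ~7,500 trials per cursor weight (15 sessions × 500 trials), sized from this error
analysis so that attenuation plus Monte-Carlo error stay inside the recovery
tolerance (|slope − weight| ≤ 0.12 on the mean over the three lags).  The worked
example in the README uses 4 × 200 trials — the scale of one participant's
data — where the same attenuation visibly pulls the slope a little below
the simulated 0.6; the effect shrinks as trials accumulate.

## Numerical choices

- End-of-movement times are interpolated between 500 Hz samples (not
  snapped to the nearest sample).
- The first path crossing defines the end; later re-crossings are ignored.
- Distance to the path is the perpendicular |y − y_path|; "maximal distance
  from the start" is Euclidean.
- The >100 ms step filter uses a strict inequality with a 1 ns guard so an
  exactly-at-floor step is invalid despite float rounding.
- Group means are unweighted; trials are summed in trial-id order so curves
  are bit-identical under permutation of the input.
- Steps delivered before movement onset (after target appearance) are
  included as selectable steps.
- Bootstrap intervals are percentile intervals over step-time pairs,
  resampled with replacement, seeded.

## File formats

Sessions are three UTF-8 CSV tables (samples, frames, trials) with
deterministic ordering; write → read → write is byte-identical (reading
uses round-trip float parsing).  Validation is total: missing columns,
non-monotone times, unknown perturbation types, orphan trial ids, steps
outside ±1, or jitter on the wrong channel are rejected with the trial id
and file row.  Movement-end annotations and exclusions are analysis-time
state and are never serialised.

## Known limitations

- The acceleration impulse response and all feedback-law parameters are
  invented defaults, not fits to human data; recovered kernel shapes are
  additionally smoothed by the 40 ms estimation window.
- The origin-slope estimator inherits errors-in-variables attenuation at
  small trial counts (see above); an attenuation-corrected estimator was
  deliberately not substituted because the plain Σtc/Σt² slope is the
  analysis under study.
- The trial-table reader accepts same-shaped tables from any source, but no
  loader for any external repository layout is provided; external data must
  be coerced into the documented dialect.
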