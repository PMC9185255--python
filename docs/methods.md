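# Methods

This note records the models, defaults and numerical choices behind
pulsecontour, and what the synthetic-data tests do and do not demonstrate.

## Signal model and conventions

A recording is a uniformly sampled single-channel cuff-pressure signal in
mmHg; sample `i` occurs at `t0 + i/fs` with `fs = 512 Hz` by default.
Indexing is 0-based and all beat windows are half-open `[onset_k,
onset_{k+1})`, so concatenating the segmented beats (plus the head before
the first onset and the tail after the last) reproduces the recording
exactly. All times reported by the package are seconds; times inside a
beat are relative to its first sample.

## Respiratory stabilization

Breathing modulates the oscillation amplitude at ~0.2–0.3 Hz. The
stabilizer is deliberately simple and fully observable:

1. per-beat amplitude anchors: `max − min` of each complete beat, placed at
   that beat's systolic-peak time;
2. a shape-preserving piecewise cubic (PCHIP) through the anchors, held
   constant beyond the first/last anchor — PCHIP cannot overshoot, so the
   interpolated envelope cannot cross zero when the anchors are positive;
3. each sample's deviation from the beat-local baseline (the beat minimum)
   is multiplied by `target/envelope`.

At least three complete beats are required; with fewer anchors the
interpolant is meaningless. The estimated modulation depth is reported as
`(max − min)/(max + min)` over the anchors. Respiration is estimated and
removed only; the package does not attempt respiratory-rate diagnostics.

## Onset detection

The paper-standard cycle onset (point A) is the local minimum preceding
the systolic upstroke. Peaks are picked on a 0.5–10 Hz band-passed copy
with a minimum spacing of `60/max_rate` (default 40–180 bpm band) and a
prominence of at least 25 % of the typical beat amplitude. Two
robustness choices matter in practice:

* the "typical beat amplitude" is the 75th percentile of candidate-peak
  prominences, not the median — when the dicrotic wave itself clears the
  peak picker, a plain median is dragged down and lets dicrotic waves pass
  as false beats;
* on a flat diastolic tail the literal `argmin` wanders with noise, so the
  onset is the **last** sample still within a noise-scaled tolerance of the
  inter-peak minimum (the upstroke foot). The tolerance is
  `max(4σ/√w, 0.5 % of the beat prominence)` with `σ` a robust
  difference-based noise estimate and `w` the smoothing window.

The first beat of a recording has no preceding diastolic tail, which
shifts its detected foot by a few samples; for essentially periodic trains
(spacing CV < 0.5 %) the first onset is instead placed one median period
before the second.

## Fiducial delineation

The beat is smoothed by a Savitzky–Golay filter (default window 25 ms,
order 3) whose `deriv=0,1,2` outputs give the signal and its analytic
first/second derivatives on the sample grid. Decision rules:

* **A**: first sample (segmentation already cut at the pre-systolic
  minimum).
* **B**: global maximum.
* **C**: among post-B local minima, the one followed by the largest
  rebound within 0.25 s (the dicrotic wave); ties break to the earliest.
  The best rebound must exceed 0.5 % of the beat's range — below that the
  "structure" is smoothing/float ripple and C, D are reported absent with
  a `no_dicrotic_structure` flag.
* **D**: highest interior local maximum after C.
* **E**: the beat's final sample. Beats end at the next cycle's onset, so
  this is the end of diastole by construction; searching the flat tail for
  a literal minimum would let noise bias every duration feature.
* **B′**: the most salient local maximum of the second derivative on the
  interior 15–75 % stretch of the B→C descent (the excluded ends carry the
  systolic peak's and the notch's own curvature), reported only when its
  height exceeds 10 % of the global |d2| peak. B′ is frequently absent on
  real contours and the generator can produce it at any saliency.

The display coefficients 5 (first derivative) and 50 (second) are stored
with the derivative set and applied only on export/plotting, never in
detection.

Each detected extremum (B, C, D) is refined by fitting a not-a-knot cubic
spline to ±10 ms of raw samples around its grid position and moving it to
the spline's extremum, clamped to ±1 sample and never across a neighboring
fiducial. A and E sit on the beat edges and are flagged
`unrefined_edge`; B′ is a curvature landmark, not an extremum, and is left
unrefined by design.

## Amplitude–time parameters

Heights are measured from the cycle-onset amplitude `h(A)` (pulse
amplitude `h(B)−h(A)`, incision height `h(C)−h(A)`) except the dicrotic
amplitude, which is `h(D)−h(E)`. The vessel/heart time split is
diastole vs systole as a fraction of the cycle; the heart fraction is
computed as `100 − vessel` so the two sum to exactly 100. Filling time is
the time for the rising limb to reach 90 % of pulse amplitude (threshold
configurable; only the normative range 0.06–0.12 s is standard, not a
formula). The "ejection" (exile-phase) duration is `t_B′ − t_A` when B′
is visible, absent otherwise.

Two recorded tensions in the normative set are carried as-is rather than
resolved: the point norm "dicrotic amplitude = ½ pulse amplitude" implies
a DWI of 50 %, outside the 63–73 % DWI band; and the reflection-time band
0.03–0.04 s is narrower than `t_D − t_C` on typical contours (0.06–0.08 s),
suggesting a different intended endpoint pair. The formulas are
configurable and verdicts report what the configured definition measures.

Absent optional features are imputed in the 21-vector with the midpoint of
their normative band (DWI 68 %, rising index 19.5 %, filling 0.09 s,
reflection 0.035 s), the point-norm fraction of pulse amplitude for the
two amplitude ratios, the anacrotic duration for the ejection phase
(B′→B limit), and a healthy 36/64 systole/diastole split of the cycle;
every imputed name is listed on the vector.

## Synthetic generator

A beat is `baseline + systolic bump + optional B′ bump + dicrotic bump`.
Bumps are asymmetric Gaussians whose width blends logistically between a
left and a right sigma — the blend keeps the composite infinitely
differentiable with its peak exactly at the bump centre; a hard piecewise
width would put a curvature jump at every peak that both the smoother and
the spline refiner turn into a systematic sub-sample bias.

Four quantities are calibrated numerically to the requested values: the
two component amplitudes by a fixed-point iteration on the measured peak
heights, and the systolic right / dicrotic left widths by a bounded
least-squares root find on (notch depth, notch time). Residuals are driven
below 1e-6 of the pulse amplitude; the ground truth returned with each
beat holds the continuous composite's extrema located to 1e-8 s, so
detector errors can be judged at sub-sample precision. Morphologies whose
notch cannot be placed where requested (too deep and too far from both
bumps) raise `CalibrationError`; the random-morphology sampler and the
cohort variant-drawer redraw such combinations, so every emitted parameter
set is realizable. The B′ coupling (bump amplitude = 0.1 × saliency ×
pulse amplitude, width 18 ms, centred at 45 % of the B→C interval) was
fixed once so that the generated shoulder's d2 saliency roughly tracks the
requested saliency on the default morphology.

Recordings concatenate per-beat evaluations of the calibrated shape with
period jitter (fractional sd, default 2 %), multiply each beat's
above-baseline pressure by `1 + depth·sin(2π f_resp t_peak)` (one factor
per beat, recorded in the truth log), and add a 0.05 Hz sinusoidal drift
and white noise. One `numpy` Generator seeded from `seed` is consumed in
documented order — drift phase, then per-beat jitter, then noise — so any
prefix of the stream is reproducible.

The presets encode the three printed age exemplars (amplitudes 8/12/22
mmHg, dicrotic indices 44/41.6/22.7 %, vessel-time fractions 64/64/49.4 %)
plus a "young-normal" textbook contour whose DWI (70 %) sits inside the
normative band; preset amplitudes stay inside the cuff's observed 8–25
mmHg oscillation band. Cohorts draw per-subject anthropometrics matched to
the preset age group and mild morphology variation (3 % sd on ratios, 8 %
on amplitude, 5 % on heart rate), with recording noise at 0.5 % of the
subject's pulse amplitude.

What the generator does **not** emulate: baseline wander from cuff
pressure ramps, motion artifacts, arrhythmic beat-to-beat morphology
change, sensor quantization, or any mechanistic (Windkessel-type)
pressure physiology. Passing tests therefore demonstrate correctness of
the contour algorithms under the stated signal model, not clinical
performance on hardware recordings.

## Classifier

The MLP is one hidden layer, logistic or tanh units, logistic outputs.
Default loss is the sum of squared errors (classical delta-rule backprop);
cross-entropy is available, where the logistic-output derivative
telescopes to `a − y`. Inputs are z-scored per feature (statistics stored
with the model) because anthropometric and timing features differ by
orders of magnitude. Weights initialize uniformly in
`[−1/√fan_in, 1/√fan_in]`, biases at zero, reproducibly from a seed.
Training is per-sample (shuffled) or full-batch; the per-epoch loss trace
is over the full dataset, and non-finite loss aborts with the epoch index.
Hidden-layer sizing is left to a seeded stratified k-fold helper that
reports per-output sensitivity and specificity for each candidate size and
makes no selection itself — rational sizing is an open empirical question.
Models persist as plain JSON (architecture, scaling statistics, weights).

## Problem sizes and runtime

The test suite and the acceptance script use a 200-beat random-morphology
sweep, 30 s single recordings for the respiratory checks, and a 100-subject
two-preset cohort at 12 s per recording — sizes at which every statistic
of interest (worst-case recovery errors, cohort mean indices, held-out
accuracy) is stable across seeds while the full suite runs in about two
minutes on one CPU. The cohort-level age-amplitude findings reported for
real subjects require the external hardware recordings and are covered
here only by the property-based synthetic suite, not by numeric
replication.
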