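# Methods

`wristmine` re-implements, as a tested library, a smartwatch-based pipeline
for recognising the daily-living activities of students and summarising
their habits: duty-cycled multi-rate wrist-sensor streams are aligned,
consolidated into fixed-length labeled windows, enriched with wavelet
subband-energy features, filtered by correlation-based feature selection,
and classified under stratified cross-validation. Because the original
cohort's data are available only on request, the package ships a synthetic
stream generator calibrated to the cohort's published per-activity summary
statistics; every claim the test suite makes is therefore a claim about
data with a known ground truth.

## The synthetic data generator

**What it emulates.** Ten daily activities (eating, running, sleeping,
classroom-session, exam, job, homework, transportation, watching TV-Series,
reading), each described by an `ActivityProfile`:

- *Episode durations* — normal with the published per-activity mean/sd,
  clipped to the published min/max. Clipping (rather than resampling) keeps
  the bias small for the heavy-tailed calibrations; the analytic clipped
  mean is exposed as `expected_duration` because for activities whose sd
  rivals the mean (job: 15,066 s sd on a 13,713 s mean) the effective mean
  shifts by up to +12%.
- *Heart rate* — a stationary AR(1) path (lag-one correlation 0.9 at 1 Hz)
  around the published activity mean, with the published marginal sd, plus
  a small per-episode baseline offset (sd 0.75 bpm).
- *Cumulative counters* — calories advance as noisy non-negative increments
  around the calibrated rate (mean episode total over mean duration);
  steps are Poisson arrivals; both are modulated by a slow within-episode
  AR(1) intensity drift (one step per 40 s duty period) and a unit-mean
  per-episode jitter. For non-locomotive activities, steps and distance
  accumulate instead as sparse compound-Poisson bursts (a coffee run, a
  bathroom trip): episode totals still match the calibration, but most
  5-minute windows see a delta of zero. The published spreads for these
  quantities are of the order of their means, which fixed the jitter scale.
- *Inertial channels* — per-activity sums of at most two sinusoids (e.g.
  ~2 Hz gait for running, ~0.4 Hz fidgeting in a classroom) plus white
  noise, scaled by a per-episode vigour factor and a within-episode
  intensity envelope. Gravity projects onto a random per-episode wrist
  orientation that drifts slowly across the episode, so raw accelerometer
  means carry orientation, not activity.
- *Skin temperature* — activity-level baseline (34.5 °C sleeping, ~33.5 °C
  otherwise) with a slow drifting offset (sd 0.3 °C) and 0.8 °C sensor
  noise.

Sensors are duty cycled with a 40 s activation period — the heart-rate
sensor wakes for 12.5% of each period, every other sensor for 5% — and
sample at different rates (gyroscope and accelerometer 8 Hz, everything
else 1 Hz; the device class's rates are not published, so these are chosen
defaults, configurable via `SensorConfig`). Day schedules place sleep after
midnight, meals inside the breakfast/lunch/dinner hour windows, and other
activities in the remaining gaps; an infeasible day (requested time beyond
24 h) is an error.

**What it does not emulate.** Device-specific calibration error, sensor
dropout beyond duty cycling, posture transitions within an episode,
mislabeling behaviour (an optional label-noise fraction could be layered on
but is off by default), battery effects, and any dependence between
activities and the calendar. Passing tests therefore demonstrate that the
pipeline is correct and that its qualitative behaviour (e.g. wavelet
features helping classification) holds on data with activity-distinct
spectra — not that the published accuracy figures are reproduced, which
would require the original request-only dataset.

**A realism note.** An early version of the generator used per-episode
constant rates with small noise. Every feature-set case then saturated near
100% cross-validated accuracy, because windows from one episode were
near-duplicates and the forest fingerprinted episodes rather than
recognising activities. The published per-activity spreads (sd of the order
of the mean for distance, steps and calories) indicate far larger
behavioural variability; the lognormal jitters, within-episode drifts and
burst counters above restore it. They make the classification task harder.

## Ingestion and consolidation

Slow sensors are *latched* to the gyroscope tick grid: each gyro-tick row
carries every channel's most recent observation (forward fill, no
interpolation). A channel first observed after a segment's first gyro tick
is back-filled from its first observation, with a warning. Segments are
contiguous (alias, activity) runs, split when a gap exceeds 600 s (the
duty-off phase is 38 s, so this never splits a live episode). Over-long
segments can be trimmed to a per-activity cap (e.g. 90 min for a classroom
session, matching class scheduling).

Consolidation is two-level: 5 s sub-windows (instantaneous channels
averaged, cumulative counters differenced) aggregated into 5 min instance
rows (mean of sub-window means; sum of sub-window deltas). Sub-window
deltas close against the previous sub-window's last reading, so summed
instance deltas equal the raw counter span exactly — a conservation law the
tests assert to 1e-9. The three sum-of-squares features (`accelXYZ`,
`gyroXYZAccel`, `gyroXYZAnguVel`) are recomputed from instance-level
channel means. A trailing partial window is kept iff at least half full;
the instance count for a segment spanning `D` seconds is
`floor(D/300) + (1 if D mod 300 >= 150)`. Timestamps are POSIX seconds
(with a fractional part at 8 Hz), windows are half-open `[start, start+w)`.

## Wavelet features

The filter family is the one-angle lattice

    h(θ) = (1 − cos θ + sin θ, 1 + cos θ + sin θ,
            1 + cos θ − sin θ, 1 − cos θ − sin θ) / (2√2),
    g_k = (−1)^k h_{3−k},

orthonormal for every θ (Σh = √2, Σh² = 1, Σg = 0, h ⊥ g). At θ = π/3 it is
exactly the Daubechies-4 filter ((1±√3)-family over 4√2); other texts place
the same filter at an offset angle (e.g. 5π/12) under a different
parametrization — the package pins the constant `DAUBECHIES4_THETA` to the
coefficients, not to any convention's angle.

The transform is the standard in-place dyadic pyramid with periodic
(circular) convolution, validated against a dense-matrix oracle and for
perfect reconstruction/Parseval to 1e-9 on dyadic lengths 8–512. With a
128-sample buffer and 4 levels, the five natural sub-bands are merged into
four reported bands — approximation ∪ deepest detail → band 0 (indices
[0,16)), then [16,32), [32,64), [64,128) — so the highest frequencies sit
in band 3. This 4-level-to-4-band merge is one defensible reading of the
band layout; it preserves the Parseval partition, which the tests assert.

Each instance window's nine inertial channel sequences are linearly
resampled *by sample index* (not wall-clock time) to 128 points before the
transform. Duty cycling leaves ~112–120 gyro samples per 5-minute window in
2 s bursts; index-based resampling keeps the within-burst spectral content
(at the 8 Hz sensor rate) intact, whereas wall-clock interpolation across
the 38 s duty gaps would destroy it. Band energies are raw sums of squared
coefficients, unnormalised: classifiers downstream are scale-tolerant, and
the s² amplitude scaling is itself a tested invariant.

## Feature selection

The selector reproduces the classic correlation-based subset pipeline from
scratch: supervised entropy/MDL discretization (recursive binary splits
accepted only when information gain beats the MDL code-length criterion),
symmetric uncertainty SU = 2·I(x;y)/(H(x)+H(y)) with SU ≡ 0 for constant
variables, the merit k·r̄cf / √(k + k(k−1)·r̄ff), and forward best-first
search that stops after 5 consecutive non-improving expansions, ties broken
by column order. The "locally predictive" post-pass some toolkits add is
deliberately omitted. In the cross-validated cases, selection runs on each
fold's training split only (verified by a leakage test); a single global
pass is available through the CLI.

## Classification

Six feature-set cases — time domain (19 features), wavelet domain (7
non-inertial time features + 36 band energies = 43), their union (55), each
with and without per-fold selection — crossed with five classifiers:

- a one-hidden-layer perceptron ((features+classes)/2 units, SGD with
  learning rate 0.3, momentum 0.2, 500 epochs, standardized inputs),
- Gaussian naive Bayes,
- a C4.5-style entropy tree (minimum leaf 2),
- a 100-tree random forest,
- a RIPPER-style rule learner, written for this package: rarest classes
  first, FOIL-gain growing on a 2/3 grow split, (p−n)/(p+n) pruning on the
  rest, and rule addition stopped when prune-set precision no longer beats
  the class prior. Under permuted labels it induces no rules and predicts
  the majority class — which is why the permutation-null check uses it: an
  unpruned forest on windowed data instead memorizes near-duplicate
  instances and lands measurably *below* the majority rate.

Folds are stratified with a fixed seed; classes smaller than the fold count
are spread one-per-fold (leave-one-out behaviour). Class imbalance is
preserved, not rebalanced. Accuracy is percent correct pooled over folds;
confusion matrices are true × predicted over the full ten-label set.

## Habit analytics

Episodes are reconstructed as contiguous (alias, activity) instance runs.
Summaries use population-form sd (an activity observed once reports sd 0).
Calorie rates are mean episode calories over mean duration, reported to
2 decimals (cal/s) and 1 decimal (cal/h); with the shipped calibration this
reproduces the published arithmetic exactly (sleeping 0.02 cal/s =
61.1 cal/h; exam 0.12 cal/s; running 103 cal/h = 51.5 cal per 30 min).
Meals classify by the episode's local integer start hour — breakfast 4–9,
lunch 10–17, dinner 18–23, all bounds inclusive; hours 0–3 are
"unclassified" rather than force-assigned. Heart-rate zones derive from
maximum heart rate 220 − age; the 50–70% moderate zone at age 23 is
98.5–137.9 bpm (the upper bound follows from the formula: 0.70 × 197 =
137.9). The habit report flags sleep under a configurable nightly goal
(default 8 h) and any activity whose minimum or mean heart rate comes
within 2 bpm of the sleeping mean.

## Numerical and statistical choices

- All randomness flows from one seed through splittable `numpy` bit
  generators; every experiment in `wristmine.experiments` is reproducible
  from its seed argument.
- Wavelet identities are asserted to 1e-12 (filters) and 1e-9 (transform);
  conservation laws to 1e-9 absolute.
- Validation problem sizes: the feature-ordering experiment uses ten
  replicate cohorts of ~600 window instances each (~6,000 in total), 10-fold
  CV and 100-tree forests; parameter recovery uses 200 episodes per
  activity; meal recovery 100 random schedules; selection noise-rejection
  100 replicates of a 500 × 13 table.
- Duration-recovery tolerances: for calibrations whose sd is of the order
  of the mean, the Monte-Carlo standard error of a 200-episode mean is
  itself ~4–5.5%, so recovery is asserted against the analytic clipped
  mean within max(5%, 3 standard errors), the standard error taken from an
  independent 200,000-draw oracle of the same sampler. Heart rate and
  calorie rate use a plain 5% band (their standard errors are well below
  it).

## Known limitations

- The generator's motion model is a two-sinusoid caricature; real wrist
  motion is broadband and transient-rich. Subband energies remain
  activity-distinct, which is what the ordering experiment requires.
- The published accuracy table of the original study is a property of its
  request-only dataset and is out of scope here; on the synthetic cohorts
  the absolute accuracies are higher than the published ones, and the
  meaningful claim is the ordering (wavelet features do not hurt, and on
  average help, the tree ensemble).
- The RIPPER-style learner is a compact re-implementation, not a
  feature-complete RIPPER (no MDL-based global optimisation passes); it is
  deterministic, fast, and sufficient for the grid's comparative role.
- `distPace` is synthesized as 1/speed (0 when stationary), which is a
  simplification of a real pace channel.
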