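# Methods

## Problem and model

The Action Research Arm Test (ARAT) rates 19 upper-limb tasks, grouped
into the grasp, grip, pinch and gross-movement domains, on an ordinal
0–3 scale per task (0 = cannot perform, 3 = normal performance), giving
a 0–57 total per arm. `aratscore` estimates these ratings from 6-axis
wrist IMU signals. The estimation pipeline treats each task execution as
one observation: a fixed 74-dimensional feature vector is classified
into a score by a per-domain ordinal model, and task scores are summed
into the total.

### Orientation filter and gravity removal

Accelerometers measure specific force — movement acceleration plus
gravity — in the moving sensor frame, so gravity must be removed before
movement features are meaningful. Orientation is tracked with a
complementary quaternion filter (scalar-first Hamilton quaternions,
sensor-to-world, world z-up):

* each step propagates the quaternion by the gyroscope rotation vector
  (strap-down integration, exact exponential map per sample);
* whenever the specific-force norm is within 0.5 g of g, the estimate
  is rotated toward the accelerometer-derived gravity direction by a
  fraction `gain` of the residual tilt angle. The 0.5 g guard suspends
  correction under high dynamics, when the accelerometer does not point
  along gravity.

The default `gain` is **0.02 per sample** (time constant ≈ 1 s at
50 Hz): small enough that reach-frequency movement acceleration
(≈ 0.3–0.7 Hz) is strongly attenuated in the tilt estimate, large
enough to absorb gyroscope noise and bias drift. Heading (yaw) is
unobservable without a magnetometer and accumulates gyro error; this is
harmless for the features used here, which are computed on vector norms
or on per-axis statistics of signals whose vertical axis is what
matters. Initial orientation is the tilt aligning the first
accelerometer sample with the vertical, heading zero.

Linear acceleration is `R(q) f − (0, 0, g)` with g fixed at 9.81 m/s².
The round-trip accuracy on default synthetic sessions (known orientation
trajectory, known world acceleration) is RMSE ≈ 0.07 m/s², versus
≈ 0.35 m/s² for uncorrected integration.

### Segmentation rules

Segments are sliced at the annotated `[t_start, t_stop)`; sequences
longer than 60 s keep their **first** 3000 samples (task timing starts
at `t_start`, so the attempt's onset is always retained). Unattempted or
missing tasks receive score 0 and a **10 s non-moving window** from the
same recording: the first 10 s window whose linear-acceleration-norm
variance is below 0.01 (m/s²)², falling back to the lowest-variance
window with a logged warning. Timestamps are seconds from recording
start; annotations share that clock.

### Features

Ten time-domain statistics per channel × six channels (world-frame
linear acceleration x/y/z, **sensor-frame** angular velocity x/y/z —
gyro is used as measured, the frame choice being configurable in
principle but not exposed) = 60, plus seven spectral statistics per
vector norm × two norms = 14. Pinned conventions:

* percentiles use linear interpolation between order statistics;
  "minimum"/"maximum" are the 5th/95th percentiles and range their
  difference;
* zero-crossing rate counts strict sign changes of the mean-removed
  channel divided by (N−1), removing duration dependence;
* kurtosis is Fisher (excess), defined as 0 for zero-variance channels;
* spectra are single un-windowed FFTs of the mean-removed norm; band
  energies are sums of squared magnitudes over half-open bins [lo, hi)
  Hz (the last band closed at the 25 Hz Nyquist), normalised by sequence
  length so segments of different duration are comparable; the five
  bands exactly partition the 0–25 Hz energy;
* the peak-frequency feature is the frequency of the largest non-DC
  magnitude bin (interpreting "maximum frequency component" as a
  Hz-valued quantity);
* the spectral centroid is Σ f·|X(f)| / Σ |X(f)| over 0–25 Hz.

### Ordinal classifier

For ordered classes c₀ < … < c_{K−1} present in the training data, K−1
independent binary logistic regressions (L2, inverse strength C = 1.0,
lbfgs) estimate P(y > c_k) on targets 1{y > c_k}. Class probabilities
follow by differencing: P(c₀) = 1 − P(y>c₀), P(c_k) = P(y>c_{k−1}) −
P(y>c_k), P(c_{K−1}) = P(y>c_{K−2}); because the binary models are fit
independently the differences can be negative, so they are clipped at 0
and renormalised to the simplex. Prediction is the arg-max with ties
broken toward the **lowest** class (conservative for a clinical score).
A domain that never exhibits a class simply omits it (e.g. a gross
domain with no score-0 observations trains on three classes and can
never predict 0).

Order of operations, chosen where the procedure was genuinely open:
**standardise (training rows only) → SMOTE on the standardised features
→ fit**. Standardising first makes SMOTE's Euclidean neighbourhoods
scale-free; fitting the standardiser on the training fold only avoids
test-set leakage. Constant features get unit scale (their standardised
values are exactly 0, the same effect as an sd floor).

### SMOTE

Every minority class is upsampled to the majority count. A synthetic row
is x + u·(x′ − x), u ~ Uniform(0,1), with x a uniformly drawn minority
row and x′ one of its k = 5 nearest same-class neighbours. Originals are
preserved; the provenance (source index, neighbour index, u) of every
synthetic row is retained on the fitted model for auditability. A class
with a single row is duplicated with Gaussian jitter (sd 1e−6, warned);
a class with no rows is simply absent. Resampling is reachable only
through the training path — predictions and evaluation always use
original rows.

### Evaluation

Leave-one-subject-out: one fold per subject, all sessions and arms of
that subject held out together. Within each fold and domain the model is
trained on the remaining subjects' (rebalanced) rows and tested on the
held-out subject's original rows; a training fold whose domain has a
single class is skipped with a warning and its rows marked unpredicted.
Training rows are canonically sorted before fitting so predictions are
invariant to input row order.

Support-weighted metrics average per-class precision/recall with weights
nᵢ/N; weighted recall then equals overall accuracy algebraically
(Σᵢ (nᵢ/N)(TPᵢ/nᵢ) = trace/N), a property the tests verify. Totals sum
the 19 task scores per (subject, session, arm); unpredicted rows count
as 0, consistent with the missing-task rule, and are logged. Both
sessions and both arms enter the clinical-vs-estimated regression as
separate observations; the grouping keys are kept in the output so other
poolings can be recomputed. Agreement is summarised by OLS slope /
intercept / R², mean error (estimated − clinical), MAE, max |error|,
RMSE and 100·RMSE/57. The ARAT's minimally detectable change
(3.5 points) and minimally clinically important difference (12–17
points) are useful external yardsticks for these errors; they are
constants for interpretation, not quantities this package computes.

## Synthetic cohort

The simulator generates the study conditions the pipeline assumes:

* **Severity.** Each subject gets a latent severity θ ∈ [0,1] per arm:
  more affected ~ N(0.45, 0.20), less affected ~ N(0.05, 0.05), both
  clipped to [0,1] and constant across sessions. The less affected arm
  therefore scores 3 on most tasks, reproducing the strong class
  imbalance such cohorts show.
* **Scores.** A task score is the number of thresholds (0.25, 0.5,
  0.75) exceeded by the ability 1 − θ + ε, ε ~ N(0, 0.08) — the
  simplest generative mechanism producing ordinal, severity-linked,
  noisy labels.
* **Signals (50 Hz).** An attempted task is a train of alternating
  minimum-jerk point-to-point reaches (the canonical smooth-movement
  profile in motor control) whose amplitude scale (0.35 / 0.7 / 1.0 of
  a 0.25 m nominal reach) and tempo (3.0 / 2.5 / 1.5 s per reach) vary
  with score 1/2/3, plus a tremor sinusoid at a random frequency in
  3–8 Hz with acceleration amplitude 1.2 / 0.5 / 0 m/s² for scores
  1/2/3. Score-0 tasks are stationary noise. Task durations are fixed
  per score (10 / 36 / 16 / 6 s for scores 0–3, all ≤ 60 s): lower
  scores take longer, and the values are free parameters of the
  simulator, not facts about any cohort.
* **Gravity and rotation.** A slow sinusoidal wrist tilt (0.3 rad,
  0.2 Hz) plus reach-locked forearm rotation define the true angular
  velocity; the orientation trajectory is its exact integral, and the
  accelerometer output is Rᵀ(a_world + g ẑ) plus white noise (0.05 m/s²
  accel, 0.02 rad/s gyro). Gravity removal is thus genuinely exercised,
  not bypassed.
* **Missingness.** Each task is unattempted with probability 0.03
  (real cohorts report a few percent), inserted as a 10 s stationary
  block with ground-truth score 0.
* **Registry.** The per-domain task split defaults to grasp 6, grip 4,
  pinch 6, gross 3 (configurable; the instrument's domain sizes are not
  modelled further) and always sums to 19.

**What the simulator does not emulate:** finger and grasp kinematics
(invisible to wrist sensors), inter-subject movement idiosyncrasy,
compensatory strategies, non-stationary tremor, annotation timing
errors, or any overlap between the feature distributions of adjacent
scores beyond sensor noise. Scores are separable by construction, so
near-perfect LOSO recovery on synthetic data demonstrates that the
pipeline is implemented correctly end to end — it does **not**
demonstrate clinical accuracy, where adjacent scores (0 vs 1, 1 vs 2)
overlap heavily and accuracies around 0.75–0.81 are the realistic
range.

## Problem sizes and determinism

The default evaluation cohort is 20 subjects × 2 sessions × 2 arms × 19
tasks = 1,520 task observations (~80 recordings of 3–10 minutes), which
the full pipeline processes in well under a minute. Every stochastic
step (simulation, SMOTE) takes an explicit seed; identical seeds give
bit-identical datasets, feature tables and predictions. Cross-validation
derives per-domain seeds deterministically from the model seed, and
training rows are sorted canonically, so results are independent of row
and fold ordering.

## Known limitations

* The complementary filter realises the principle of
  accelerometer-corrected inclination but is not claimed to be
  numerically equivalent to any particular published fusion algorithm.
* Heading drift is uncorrected (no magnetometer); features are chosen
  to be insensitive to it, but yaw-dependent quantities would not be.
* The feature set omits kinematic quality metrics (endpoint smoothness,
  joint angles); the classifier sees only wrist dynamics.
* Band-energy normalisation by sequence length and the per-transition
  zero-crossing rate are reasonable pinned conventions, but other
  normalisations exist and would change absolute feature values.
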