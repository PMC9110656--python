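# aratscore

Estimation of **Action Research Arm Test (ARAT)** scores from two
wrist-worn inertial sensors.

The ARAT is a standard clinical assessment of upper-limb activity
capacity after stroke: 19 reach-and-grasp tasks in four domains (grasp,
grip, pinch, gross movements), each rated by a trained evaluator on an
ordinal 0–3 scale, for a total of 0–57 points per arm. `aratscore`
implements a sensor-based estimation pipeline for these scores from
6-axis wrist IMU data (tri-axial accelerometer + gyroscope, 50 Hz, one
sensor per wrist):

1. **Sensor fusion and gravity removal** — a complementary quaternion
   filter tracks sensor orientation (gyroscope strap-down integration
   with accelerometer tilt correction; heading is unobservable without a
   magnetometer and left as integrated). Specific force is rotated into
   a z-up world frame and *g* subtracted, yielding pure movement
   acceleration.
2. **Task segmentation** — recordings are cut at the annotated per-task
   start/stop times, capped at 60 s; unattempted tasks are scored 0 and
   replaced by a 10 s non-moving window from the same recording.
3. **74-feature extraction** — 60 time-domain features (mean, std, 5th/
   95th percentiles, range, mean absolute deviation, IQR, upper
   quartile, zero-crossing rate, kurtosis; per each of the six channels)
   plus 14 frequency-domain features (peak frequency, spectral energy in
   0–5/5–10/10–15/15–20/20–25 Hz bands, spectral centroid; per the
   acceleration and angular-velocity norms).
4. **Ordinal classification** — one Frank–Hall ordinal logistic
   classifier per ARAT domain: K−1 L2-regularised binary models estimate
   the cumulative probabilities P(y > k), composed by differencing into
   class probabilities. Features are standardised on the training fold
   and the training set rebalanced with SMOTE (classes upsampled to the
   majority count by interpolating between same-class nearest
   neighbours); test data is never resampled.
5. **Evaluation** — leave-one-subject-out cross-validation (all sessions
   and arms of the held-out subject), support-weighted accuracy /
   precision / recall and confusion matrices per domain, and per-arm
   total scores (sum of 19 task scores) compared with the clinical
   totals via OLS regression, ME, MAE, max error, RMSE and relative
   error (% of 57).

Because clinical recordings cannot be redistributed, the package ships a
first-class **synthetic ARAT-session simulator**: a latent
ordered-threshold severity model produces ordinal task scores, and each
task is rendered as minimum-jerk reach cycles with score-dependent
duration, amplitude and band-limited (3–8 Hz) tremor, with gravity
injected through a synthetic wrist-tilt orientation trajectory. This
gives every stage — including gravity removal — a ground truth to
recover.

## Worked example

```python
from aratscore import PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(simulation=SimulationConfig(n_subjects=20, seed=0))
report, predictions = run_pipeline(config)
for domain, m in report.per_domain.items():
    print(domain, round(m["weighted_accuracy"], 3))
print({k: round(v, 3) for k, v in report.agreement.items()})
```

prints (seed 0, default 20-subject, 2-session cohort):

```
grasp 1.0
grip 1.0
pinch 0.998
gross 1.0
{'slope': 0.999, 'intercept': 0.077, 'r_squared': 1.0, 'mean_error': 0.025,
 'mean_absolute_error': 0.025, 'max_absolute_error': 2.0, 'rmse': 0.224,
 'relative_error_pct': 0.392}
```

Per-domain weighted accuracies near 1.0 mean the LOSO-evaluated
classifiers recover almost every synthetic task score; `r_squared` is
the OLS fit between clinical and estimated per-arm totals, and
`relative_error_pct` expresses the total-score RMSE as a percentage of
the 57-point maximum. The synthetic cohort is score-separable by
construction, so recovery is near-perfect — see `docs/methods.md` for
what this does and does not demonstrate about clinical data.

The same workflow is available from the shell:

```bash
aratscore simulate --out data/ --seed 0
aratscore extract --recordings data/recordings --annotations data/annotations.csv --out features.csv
aratscore evaluate --features features.csv --out report/
# or all stages at once:
aratscore run-all --out results/ --seed 0
```

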