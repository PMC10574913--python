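# Methods

## Scope and design

glycast compares three ways of predicting the three-level glycemia class
(hypo < 70 mg/dL, norm 70–180, hyper > 180) from a 15-min CGM series, at
15-min and 1-h lead times.  Per patient, models are estimated on a
chronological in-sample window and evaluated rolling through the
out-of-sample remainder; per-patient confusion matrices are aggregated by
summing counts across patients and row-normalizing the sum.

## Virtual-patient simulator

Real clinical CGM cohorts are access-restricted, so the package generates
its own study data.  The generator has two parts.

**Protocol.**  Per day and patient: three meals (pivots 07:00 / 12:00 /
18:00, 60 g each) and three snack slots (10:00 / 15:00 / 21:00, 15 g),
each snack taken independently with probability 0.5 — an expected 1.5
snacks/day.  Times are jittered uniformly ±30 min, sizes ±25%.  The pivot
sizes and jitter widths are package defaults (all overridable); the slot
count, snack probability and cohort layout (10 patients × 3 age groups ×
10 days) are the study conditions.

**Glucose dynamics.**  A deliberately lightweight linear model instead of
a full metabolic simulator: gut carbohydrate mass Q is absorbed with
first-order kinetics (time constant τ_m, 30–50 min), raising glucose by
`carb_response_gain` (mg/dL per gram absorbed); each meal simultaneously
loads an insulin-action compartment with time constant 3·τ_m whose outflow
drags glucose down, scaled by `insulin_sensitivity`; glucose otherwise
relaxes toward `basal_glucose` at `clearance_rate` (per minute).  The
slower insulin kinetics produce the characteristic post-prandial rise
followed by an undershoot below basal — the mechanism that generates
hypoglycemic episodes.  Integration is forward Euler at 1-min steps,
clipped to the physical sensor range [20, 600] mg/dL; i.i.d. Gaussian
sensor noise (default sd 5 mg/dL) is added on top of the smoothed
trajectory.  The linear system has a closed-form solution, which the test
suite uses as an oracle for the integrator.

Age-group parameter ranges give children the widest excursions (highest
carb gain, slowest clearance) and adults the narrowest, with adolescents
between.  The ranges were fixed once so that the default-seed cohort shows
a realistic type-1-diabetes class mix — on the default cohort roughly 3–4%
of observations below 70 mg/dL and 10–12% above 180, with every patient
experiencing hyperglycemia and most experiencing hypoglycemia.

**Seeding.**  Each patient's streams derive from
`SeedSequence(master_seed, spawn_key=(group, patient))`, split into
parameter, schedule and noise children, so any patient is reproducible in
isolation and enlarging the cohort never perturbs existing patients.

**What the simulator does not emulate.**  Insulin pump dynamics, sensor
drift/dropout/compression artifacts, autocorrelated sensor noise, exercise,
circadian insulin-sensitivity variation, and inter-day habit structure.
Consequences for interpretation are discussed under *Known limitations*.

## Preprocessing

Input records (simulator output or real exports with the same
`patient_id,timestamp,cgm_mg_dl,insulin_u,cho_g` schema) are cleaned and
binned to a 15-min grid:

* glucose outside [20, 600] mg/dL is dropped as a bad entry;
* readings fall into half-open bins [t, t+15) labeled by the left edge
  (a bin never contains information from after its label); bin glucose is
  the mean of contributions, carbs and insulin are summed (mass
  conserved);
* gaps of at most 60 min are bridged by linear interpolation; longer gaps
  start a new *segment*, and no window, lag or target computation ever
  crosses a segment boundary;
* patients with fewer than 16 usable grid points are excluded with a
  warning;
* duplicate timestamps collapse to the mean of their numeric fields.

The in/out-of-sample split is chronological at 75% of grid points per
patient (configurable); every training timestamp strictly precedes every
evaluation timestamp.

## Features and targets

All features are computed per segment and are strictly causal.  Window
sizes {4, 8, 12} (1–3 h) are used simultaneously as parallel columns —
the union carries more information than any single choice and each column
remains individually interpretable.  Two conventions for degenerate
windows: a flat rolling range (max = min, common on night-time plateaus)
yields oscillator 0.5 (mid-range) rather than a dropped row; zero trailing
volatility makes relative speed undefined and the row is dropped, since an
unbounded ratio has no meaningful magnitude.  Lags 1–12 of every feature
are appended; rows with any undefined entry, and rows whose target would
cross a segment boundary, are removed.  The target is the glycemia class
`horizon` steps ahead; each model sees exactly one horizon's target.
Features are stored raw; z-scoring (with in-sample statistics only) is
applied inside the logistic and LSTM fitters.

## Models

**ARIMA** (statsmodels SARIMAX).  Fit on glucose levels with d = 1, so the
model forecasts CGM differences; (p, q) are chosen by lowest AIC over
{0..3}² (fixed-order override available).  For the 1-h task the series is
resampled to hourly points and forecast one step ahead; iterating four
15-min steps is available behind a flag.  Out-of-sample evaluation is
rolling with frozen parameters: the Kalman filter state advances over
observed history, nothing is refit — mirroring deployment and keeping
runtime linear.  Forecast levels map through the class thresholds, so the
predicted class is by construction the threshold image of the predicted
level.

**Multinomial logistic regression** (scikit-learn).  L2-regularized
(strength 1.0 by default), trained on the standardized feature frame.
Class weighting defaults to `balanced`: hypoglycemia is rare (a few
percent of observations) and an unweighted fit sacrifices nearly all hypo
recall for a marginal accuracy gain — the balanced default trades ~0.5
accuracy points for a large gain in the clinically critical class.
Probability vectors are always emitted over the full three-class simplex,
with zero mass on classes unseen in training.

**LSTM** (numpy, in-package).  No deep-learning framework is required: the
network (default one layer of 32 units, softmax head) with full BPTT and
Adam is implemented in `glycast.models._rnn` and validated against
numerical gradients.  Each frame row becomes a sequence of 12 consecutive
steps of the *unlagged* feature vector, reconstructed from the row's lag
columns — informationally identical to the flat lagged row (a flat mode
exists for parity checks) but in the natural recurrent form.  Training
uses weighted cross-entropy (balanced by default, as above), batches of
64, learning rate 3e-3, at most 40 epochs with early stopping (patience 5)
on the chronological tail 15% of the in-sample sequences; the best
validation state is restored.  Initialization and shuffling flow from one
seed, making training bit-reproducible on CPU.  The deliberately small
architecture keeps a per-patient fit to a few seconds.

Prediction ties (equal class probabilities) break toward the lower class
in the fixed order hypo < norm < hyper.

## Evaluation

Confusion matrices are 3×3, rows = true class, in the fixed class order.
The row-normalized view divides each row by its true-class total (×100);
rows with no true instances are reported missing, not zero.  Aggregation
across patients sums counts first and normalizes the sum, so aggregate
accuracy equals pooled-prediction accuracy.  Scores: per-class recall and
precision, F1, and accuracy = trace/total; undefined ratios propagate as
missing.  Report files round percentages to whole percent for the
human-readable view (rounded rows may sum to 99 or 101 — a noted cosmetic
effect) and keep full precision in JSON.

## Problem sizes

Defaults reproduce the study protocol: 30 patients × 10 days.  The test
suite and the examples exercise the pipeline on reduced cohorts — the
model-ordering checks use 2 patients per age group × 8 days (≈4600
out-of-sample predictions per model/horizon), chosen as the package's own
desk-scale default for routine verification; the full cohort runs through
the same code path via `glycast run-all`.

## Known limitations

* The glucose model is linear; it omits physiological nonlinearities
  (insulin saturation, renal clearance above ~180 mg/dL, counter-regulatory
  response).  Its near-deterministic smooth dynamics make a well-specified
  ARIMA close to the Bayes bound for one-step-ahead class prediction, so
  15-min comparisons on synthetic data flatter ARIMA relative to what is
  observed on real sensor data; the 1-h comparisons (where hourly
  resampling erases short hypoglycemic dips regardless of model quality)
  transfer more faithfully.
* Sensor noise is white; real CGM error is autocorrelated and
  drift-prone, which would further disadvantage level-forecasting models.
* Insulin dosing is folded into the glucose dynamics; the `insulin_u`
  column exists for schema compatibility with real exports but is empty in
  simulator output and unused by the models.
* Passing tests on synthetic data demonstrate the correctness of the
  pipeline's mechanics (causality, splits, formulas, aggregation), not
  clinical performance.
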