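# glycast

Glycemia-class forecasting from continuous glucose monitoring (CGM) time
series: a tested pipeline that simulates a virtual type-1-diabetes cohort,
engineers rolling-window CGM features, and compares three forecasting
approaches — ARIMA, multinomial logistic regression, and an LSTM network —
at predicting hypoglycemia, euglycemia and hyperglycemia 15 minutes and
1 hour ahead.

## The problem

People with type 1 diabetes wearing a CGM sensor need advance warning of
dangerous glucose excursions: hypoglycemia (glucose < 70 mg/dL) demands an
immediate fast-acting carbohydrate, hyperglycemia (> 180 mg/dL) an insulin
or lifestyle adjustment.  The clinically useful object is not the exact
future glucose value but its *class*:

```
GC(t) = +1 (hyper)  if CGM(t) > 180 mg/dL
         0 (norm)   if 70 ≤ CGM(t) ≤ 180
        −1 (hypo)   if CGM(t) < 70
```

glycast frames the task as three-class classification at two horizons
(1 step = 15 min and 4 steps = 1 h on a 15-min grid) and asks which model
family serves which horizon best.

## The feature set

From the CGM series alone, the pipeline derives at each time t (window
sizes M, N ∈ {4, 8, 12} grid steps, i.e. 1–3 hours):

| feature | formula |
|---|---|
| differences | dCGM(t) = CGM(t) − CGM(t−1); d²CGM(t) = dCGM(t) − dCGM(t−1) |
| rolling range | RollingMIN/MAX(t, N) over CGM(t−N+1) … CGM(t) |
| range oscillator | (CGM(t) − RollingMIN) / (RollingMAX − RollingMIN) ∈ [0, 1] |
| MAD volatility | mean of \|dCGM\| over the last M steps |
| relative speed | RS(t, M) = dCGM(t) / MAD(t−1, M) |

plus lags 1–12 of each, strictly causal (no value in row t uses data after
t, and windows never cross sensor-gap boundaries).  The logistic and LSTM
models consume these features; ARIMA consumes the raw level series (d = 1,
so it forecasts CGM differences), converts forecasts back to levels and
maps them through the class thresholds.  For the 1-h horizon ARIMA
resamples to a 60-min grid and forecasts one step.

Because real clinical CGM datasets are access-restricted, the package ships
a virtual-patient simulator: 10 patients per age group (adults,
adolescents, children) × 10 days, three randomized meals per day plus up to
three snacks each taken with probability 0.5 (≈1.5 snacks/day), glucose
driven by a linear gut-absorption / insulin-action / clearance model with
additive Gaussian sensor noise.  The simulator is a statistical stand-in:
it reproduces meal-driven excursions into all three classes, not
physiology.

## Worked example

`examples/compare_models.py` simulates six patients (two per age group,
eight days), splits each series chronologically 75/25, trains all three
models at both horizons and prints the aggregated out-of-sample grid:

```
model      horizon   hyper   norm   hypo  accuracy
arima      15min      0.85   0.99   0.65     0.954
arima      1h         0.10   1.00   0.06     0.840
logistic   15min      0.88   0.95   0.85     0.935
logistic   1h         0.70   0.90   0.65     0.855
lstm       15min      0.90   0.90   0.96     0.906
lstm       1h         0.79   0.80   0.93     0.808
```

The hyper/norm/hypo columns are per-class recalls (the diagonal of the
row-normalized confusion matrix).  The headline pattern: ARIMA's
hypoglycemia recall collapses at the 1-h horizon (0.06 — the hourly
resampling smooths right over short hypo dips), while the feature-based
models, trained with balanced class weights, retain it (LSTM 0.93).  On
this smooth synthetic cohort ARIMA is very strong at 15 min; on real
sensor data, where the dynamics fit an ARIMA far less well, feature-based
classifiers overtake it there too.

Other entry points:

```bash
python examples/simulate_cohort.py      # cohort generation + class mix
python examples/engineer_features.py    # the design matrix for one patient
glycast run-all --seed 0 --out myrun    # full pipeline via the CLI
glycast simulate / preprocess / featurize / train / evaluate / report
                                        # the same pipeline stage by stage
```

Every run writes `scores.json` / `scores.csv` (the comparative grid),
per-model confusion matrices (counts and row-normalized percentages),
per-patient scores, prediction CSVs and a manifest with the config hash
and seed, so any run is exactly reproducible.

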