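"""Engineer the rolling-window feature set for one simulated patient.

Simulates one patient, resamples the minute trace to the 15-min grid, and
builds the design matrix: CGM differences, rolling range, range oscillator,
MAD volatility and relative speed at window sizes 4/8/12, each with lags up
to 12, plus the glycemia class one step (15 min) ahead as the target.
"""

from glycast import FeatureSpec, SimConfig, build_feature_matrix, generate_cohort, write_dataset
from glycast.preprocess import clean_and_resample, read_dataset

config = SimConfig(n_patients_per_group=1, n_days=6, age_groups=("adults",), master_seed=1)
write_dataset(generate_cohort(config), "scratch_example_dataset.csv")

records = read_dataset("scratch_example_dataset.csv")
pid, rec = next(iter(records.items()))
series = clean_and_resample(rec, pid)
print(f"{pid}: {len(series)} grid points on the 15-min grid")

frame = build_feature_matrix(series, FeatureSpec(), horizon_steps=1)
base_cols = [c for c in frame.columns if "_lag" not in c and c not in ("patient_id", "target")]
print(f"feature matrix: {frame.shape[0]} rows x {frame.shape[1]} columns "
      f"({len(base_cols)} base features x 13 lags + target)")
print("\nlatest engineered values (unlagged):")
print(frame[base_cols].tail(3).round(3).to_string())
print("\ntarget distribution (class 15 min ahead):")
print(frame["target"].value_counts().rename({-1: "hypo", 0: "norm", 1: "hyper"}).to_string())
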