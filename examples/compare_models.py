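"""Run the full comparative study on a small synthetic cohort.

Simulates six virtual patients (two per age group, eight days each),
splits every patient's series chronologically 75/25, trains ARIMA,
multinomial logistic regression and the LSTM at the 15-min and 1-h
horizons, and prints the aggregated out-of-sample recall/accuracy grid.
Watch the hypoglycemia row: the hourly-resampled ARIMA loses almost all
sensitivity at the 1-h horizon while the feature-based models keep it.
"""

from glycast import SimConfig
from glycast.pipeline import RunConfig, run_pipeline

config = RunConfig(
    sim=SimConfig(n_patients_per_group=2, n_days=8),
    out_dir="scratch_example_run",
    seed=0,
    log_level="WARNING",
)
grid = run_pipeline(config)

print(f"{'model':<10} {'horizon':<8} {'hyper':>6} {'norm':>6} {'hypo':>6} {'accuracy':>9}")
for model, horizons in grid.items():
    for label, sc in horizons.items():
        print(f"{model:<10} {label:<8} {sc['recall_hyper']:6.2f} {sc['recall_norm']:6.2f} "
              f"{sc['recall_hypo']:6.2f} {sc['accuracy']:9.3f}")
print("\nrows are per-class recall; full report files are in scratch_example_run/")
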