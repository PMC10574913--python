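"""Simulate a small virtual-patient cohort and summarize its glycemia mix.

Builds three virtual type-1-diabetes patients (one per age group) over six
days of minute-resolution CGM, then reports how much time the pooled cohort
spends below 70 (hypo), between 70 and 180 (normal) and above 180 mg/dL
(hyper).  A realistic cohort spends most time in range, a sizable share
above range after meals, and a few percent below range.
"""

import numpy as np

from glycast import SimConfig, generate_cohort

config = SimConfig(n_patients_per_group=1, n_days=6, master_seed=42)
traces = generate_cohort(config)

glucose = np.concatenate([t.noisy_glucose for t in traces])
print(f"patients: {len(traces)}, minutes each: {len(traces[0].timestamps)}")
print(f"glucose range: {glucose.min():.0f}-{glucose.max():.0f} mg/dL")
print(f"time hypo  (<70):   {100 * (glucose < 70).mean():.1f}%")
print(f"time norm  (70-180): {100 * ((glucose >= 70) & (glucose <= 180)).mean():.1f}%")
print(f"time hyper (>180):  {100 * (glucose > 180).mean():.1f}%")
for t in traces:
    snacks = sum(e.is_snack for e in t.meal_events)
    print(f"  {t.patient_id}: {len(t.meal_events)} intake events, {snacks} snacks over {config.n_days} days")
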