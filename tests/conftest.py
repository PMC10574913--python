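"""Shared fixtures: small simulated patients and cleaned series."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from glycast.preprocess import GlucoseSeries
from glycast.simulate import (
    SimConfig,
    VirtualPatientParams,
    generate_meal_schedule,
    simulate_glucose,
)


def make_series(cgm, start="2023-01-01", patient_id="p1", segment_ids=None, grid_min=15) -> GlucoseSeries:
    """A GlucoseSeries on a regular grid from a plain array."""
    cgm = np.asarray(cgm, dtype=float)
    if segment_ids is None:
        segment_ids = np.zeros(len(cgm), dtype=np.int64)
        index = pd.date_range(start, periods=len(cgm), freq=f"{grid_min}min")
    else:
        segment_ids = np.asarray(segment_ids, dtype=np.int64)
        # insert a one-step hole at each segment change so timestamps honour it
        index = []
        t = pd.Timestamp(start)
        step = pd.Timedelta(minutes=grid_min)
        for i in range(len(cgm)):
            if i and segment_ids[i] != segment_ids[i - 1]:
                t += 8 * step  # a gap too long to interpolate
            index.append(t)
            t += step
        index = pd.DatetimeIndex(index)
    return GlucoseSeries(
        patient_id=patient_id, timestamps=index, cgm=cgm, segment_ids=segment_ids,
        grid_min=grid_min,
    )


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    return SimConfig(n_patients_per_group=1, n_days=6, master_seed=7)


@pytest.fixture(scope="session")
def one_patient_trace(tiny_config):
    params = VirtualPatientParams(
        patient_id="vp1", age_group="adults", basal_glucose=120.0,
        insulin_sensitivity=1.1, carb_response_gain=6.0,
        meal_absorption_tau=40.0, clearance_rate=0.016,
    )
    schedule = generate_meal_schedule(tiny_config, 11)
    return simulate_glucose(params, schedule, tiny_config, 13)


@pytest.fixture(scope="session")
def one_patient_series(one_patient_trace) -> GlucoseSeries:
    """The trace resampled to the 15-min grid (single segment)."""
    cgm = one_patient_trace.noisy_glucose.reshape(-1, 15).mean(axis=1)
    idx = one_patient_trace.timestamps[::15]
    return GlucoseSeries(
        patient_id="vp1", timestamps=idx, cgm=cgm,
        segment_ids=np.zeros(len(cgm), dtype=np.int64),
    )
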