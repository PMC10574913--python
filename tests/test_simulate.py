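"""Simulator protocol: meal schedules, glucose dynamics, determinism, IO."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from glycast.preprocess import read_dataset
from glycast.simulate import (
    AGE_GROUP_PARAM_RANGES,
    MealEvent,
    SimConfig,
    VirtualPatientParams,
    generate_cohort,
    generate_meal_schedule,
    patient_seed_sequence,
    simulate_glucose,
    write_dataset,
)


def _flat_params(**overrides):
    base = dict(
        patient_id="t", age_group="adults", basal_glucose=110.0,
        insulin_sensitivity=1.0, carb_response_gain=5.0,
        meal_absorption_tau=40.0, clearance_rate=0.02,
    )
    base.update(overrides)
    return VirtualPatientParams(**base)


class TestMealSchedule:
    def test_snack_probability_extremes(self):
        cfg0 = SimConfig(snack_probability=0.0, n_days=4)
        ev = generate_meal_schedule(cfg0, 1)
        assert len(ev) == 12 and not any(e.is_snack for e in ev)
        cfg1 = SimConfig(snack_probability=1.0, n_days=4)
        ev = generate_meal_schedule(cfg1, 1)
        assert len(ev) == 24 and sum(e.is_snack for e in ev) == 12

    def test_mean_snacks_per_day_near_protocol_value(self):
        """Three slots at probability 0.5 -> ~1.5 snacks/day over 300
        patient-days, within binomial Monte-Carlo error."""
        cfg = SimConfig()
        total, days = 0, 0
        for p in range(30):
            ev = generate_meal_schedule(cfg, patient_seed_sequence(0, 0, p))
            total += sum(e.is_snack for e in ev)
            days += cfg.n_days
        assert 1.35 <= total / days <= 1.65

    def test_times_and_sizes_jitter_around_pivots(self):
        cfg = SimConfig(n_days=30, snack_probability=1.0)
        ev = generate_meal_schedule(cfg, 3)
        breakfast = [e for e in ev if not e.is_snack and e.timestamp.hour < 10]
        pivot = 7 * 60
        for e in breakfast:
            minutes = e.timestamp.hour * 60 + e.timestamp.minute
            assert abs(minutes - pivot) <= cfg.time_jitter_min + 0.5
            assert 60.0 * 0.75 <= e.carbs_g <= 60.0 * 1.25

    def test_deterministic_given_seed(self):
        cfg = SimConfig()
        assert generate_meal_schedule(cfg, 5) == generate_meal_schedule(cfg, 5)
        assert generate_meal_schedule(cfg, 5) != generate_meal_schedule(cfg, 6)


class TestGlucoseDynamics:
    def test_no_meals_no_noise_stays_at_basal(self):
        cfg = SimConfig(n_days=1, sensor_noise_sd=0.0)
        trace = simulate_glucose(_flat_params(), [], cfg, 0)
        np.testing.assert_allclose(trace.smoothed_glucose, 110.0)
        np.testing.assert_array_equal(trace.noisy_glucose, trace.smoothed_glucose)

    def test_single_meal_matches_closed_form(self):
        """With negligible insulin action the model is the classic linear
        absorption/clearance cascade; the discrete trace must track the
        continuous closed-form solution."""
        cfg = SimConfig(n_days=1, sensor_noise_sd=0.0)
        params = _flat_params(insulin_sensitivity=1e-9)
        t0 = dt.datetime(2023, 1, 1, 6, 0)
        meal = MealEvent(t0, 60.0, False)
        trace = simulate_glucose(params, [meal], cfg, 0)
        a, k, D, gain, basal = (
            1 / params.meal_absorption_tau, params.clearance_rate, 60.0,
            params.carb_response_gain, params.basal_glucose,
        )
        # the discrete update applies the impulse inside its own minute, so
        # the trace leads the continuous solution by one step
        t = np.arange(1, 18 * 60 + 1)
        closed = basal + D * gain * a / (a - k) * (np.exp(-k * t) - np.exp(-a * t))
        sim = trace.smoothed_glucose[6 * 60 :]
        np.testing.assert_allclose(sim, closed[: len(sim)], atol=2.5)
        peak = int(np.argmax(sim))
        assert sim[peak] > basal + 50
        assert np.all(np.diff(sim[peak:]) <= 1e-9)  # monotone relaxation

    def test_insulin_action_produces_undershoot(self):
        cfg = SimConfig(n_days=1, sensor_noise_sd=0.0)
        params = _flat_params(insulin_sensitivity=1.3, carb_response_gain=7.0)
        meal = MealEvent(dt.datetime(2023, 1, 1, 6, 0), 70.0, False)
        trace = simulate_glucose(params, [meal], cfg, 0)
        assert trace.smoothed_glucose.min() < params.basal_glucose - 5

    def test_zero_noise_identity_and_noise_seed_independence(self):
        cfg = SimConfig(n_days=1, sensor_noise_sd=0.0)
        sched = generate_meal_schedule(cfg, 2)
        t1 = simulate_glucose(_flat_params(), sched, cfg, 1)
        t2 = simulate_glucose(_flat_params(), sched, cfg, 99)
        np.testing.assert_array_equal(t1.noisy_glucose, t1.smoothed_glucose)
        # smoothed trajectory never depends on the noise seed
        cfg_n = SimConfig(n_days=1, sensor_noise_sd=8.0)
        n1 = simulate_glucose(_flat_params(), sched, cfg_n, 1)
        n2 = simulate_glucose(_flat_params(), sched, cfg_n, 2)
        np.testing.assert_array_equal(n1.smoothed_glucose, n2.smoothed_glucose)
        assert not np.array_equal(n1.noisy_glucose, n2.noisy_glucose)

    def test_event_outside_range_rejected(self):
        cfg = SimConfig(n_days=1)
        late = MealEvent(dt.datetime(2023, 1, 5, 8, 0), 40.0, False)
        with pytest.raises(ValueError):
            simulate_glucose(_flat_params(), [late], cfg, 0)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(SimConfig(n_patients_per_group=3, n_days=3, master_seed=1))


class TestCohort:
    def test_cohort_shape(self, cohort):
        assert len(cohort) == 9  # patients per group x groups
        for tr in cohort:
            assert len(tr.timestamps) == 3 * 1440  # 1-min samples per day

    def test_glucose_stays_in_physical_bounds(self, cohort):
        for tr in cohort:
            assert tr.noisy_glucose.min() >= 20.0 and tr.noisy_glucose.max() <= 600.0

    def test_same_seed_reproducible_different_seed_not(self):
        cfg = SimConfig(n_patients_per_group=1, n_days=2, master_seed=4)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.noisy_glucose, y.noisy_glucose)
        c = generate_cohort(cfg.with_(master_seed=5))
        assert not np.array_equal(a[0].noisy_glucose, c[0].noisy_glucose)

    def test_adding_patients_preserves_existing_streams(self):
        small = generate_cohort(SimConfig(n_patients_per_group=1, n_days=2, master_seed=4))
        big = generate_cohort(SimConfig(n_patients_per_group=2, n_days=2, master_seed=4))
        by_id = {t.patient_id: t for t in big}
        for tr in small:
            np.testing.assert_array_equal(tr.noisy_glucose, by_id[tr.patient_id].noisy_glucose)

    def test_default_cohort_covers_all_three_classes(self):
        traces = generate_cohort(SimConfig(n_patients_per_group=2, n_days=5))
        g = np.concatenate([t.noisy_glucose for t in traces])
        assert (g < 70).any() and (g > 180).any() and ((g >= 70) & (g <= 180)).any()

    def test_parameter_draws_respect_group_ranges(self):
        ranges = AGE_GROUP_PARAM_RANGES["children"]
        assert ranges["carb_response_gain"][0] > AGE_GROUP_PARAM_RANGES["adults"]["carb_response_gain"][0]
        assert ranges["clearance_rate"][1] < AGE_GROUP_PARAM_RANGES["adults"]["clearance_rate"][1]


class TestDatasetIO:
    def test_row_count_and_round_trip(self, tmp_path):
        cfg = SimConfig(n_patients_per_group=1, n_days=1, master_seed=2,
                        age_groups=("adults",))
        traces = generate_cohort(cfg)
        path = tmp_path / "ds.csv"
        write_dataset(traces, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 + 1440  # header + one row per minute
        records = read_dataset(path)
        assert list(records) == [traces[0].patient_id]
        rec = records[traces[0].patient_id]
        np.testing.assert_allclose(
            rec["cgm_mg_dl"].to_numpy(), np.round(traces[0].noisy_glucose, 2)
        )
        # minutes without a meal carry cho_g == 0, meal minutes the carbs
        assert rec["cho_g"].fillna(0).sum() == pytest.approx(
            round(sum(e.carbs_g for e in traces[0].meal_events), 1), abs=0.1
        )

    def test_same_seed_identical_bytes(self, tmp_path):
        cfg = SimConfig(n_patients_per_group=1, n_days=1, master_seed=3)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_dataset(generate_cohort(cfg), p1)
        write_dataset(generate_cohort(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_traces_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_dataset([], tmp_path / "x.csv")


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(snack_probability=1.5)
    with pytest.raises(ValueError):
        SimConfig(n_days=0)
    with pytest.raises(ValueError):
        SimConfig(meal_size_pivot_g=(60.0, -1.0, 60.0))
    with pytest.raises(ValueError):
        VirtualPatientParams(
            patient_id="x", age_group="adults", basal_glucose=300.0,
            insulin_sensitivity=1.0, carb_response_gain=5.0,
            meal_absorption_tau=40.0, clearance_rate=0.02,
        )
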