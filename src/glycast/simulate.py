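"""Virtual-patient CGM cohort simulator.

Generates minute-resolution continuous-glucose-monitor traces for a cohort
of virtual type-1-diabetes patients, ten per age group by default, each
spanning ten days with three randomized meals per day and up to three
optional snacks.  Glucose dynamics follow a deliberately lightweight linear
two-compartment model — gut carbohydrate absorption with first-order
kinetics raising glucose, a slower meal-proportional insulin-action
compartment dragging it down (which produces realistic post-prandial
undershoot into hypoglycemia), and relaxation toward a basal level — with
additive Gaussian sensor noise on top of the smoothed trajectory.

The simulator is a statistical stand-in for a full physiological T1D
simulator: it reproduces the structure downstream code needs (meal-driven
excursions into all three glycemia classes, 1-min sampling, sensor noise),
not metabolic detail.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "MealEvent",
    "VirtualPatientParams",
    "RawTrace",
    "generate_meal_schedule",
    "simulate_glucose",
    "generate_cohort",
    "write_dataset",
    "DATASET_COLUMNS",
]

#: CSV schema shared by the simulator output and the real-data reader.
DATASET_COLUMNS = ["patient_id", "timestamp", "cgm_mg_dl", "insulin_u", "cho_g"]

#: Hard physical bounds on any glucose value the simulator emits (mg/dL).
GLUCOSE_FLOOR = 20.0
GLUCOSE_CEIL = 600.0

# Insulin-action time constant as a multiple of the gut-absorption time
# constant; slower insulin kinetics are what create the post-meal undershoot.
_INSULIN_TAU_FACTOR = 3.0


def _parse_clock(s: str) -> int:
    """'HH:MM' -> minutes since midnight."""
    h, m = s.split(":")
    return int(h) * 60 + int(m)


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings.

    Defaults encode the study protocol: 10 patients per age group, 10 days,
    3 meals/day plus up to 3 snacks each taken with probability 0.5, meal
    and snack times/sizes randomized around pivot values.
    """

    n_patients_per_group: int = 10
    age_groups: tuple[str, ...] = ("adults", "adolescents", "children")
    n_days: int = 10
    meal_pivot_times: tuple[str, str, str] = ("07:00", "12:00", "18:00")
    snack_pivot_times: tuple[str, str, str] = ("10:00", "15:00", "21:00")
    snack_probability: float = 0.5
    meal_size_pivot_g: tuple[float, float, float] = (60.0, 60.0, 60.0)
    snack_size_pivot_g: tuple[float, float, float] = (15.0, 15.0, 15.0)
    time_jitter_min: float = 30.0
    size_jitter_frac: float = 0.25
    sensor_noise_sd: float = 5.0
    master_seed: int = 0
    start_date: dt.date = field(default_factory=lambda: dt.date(2023, 1, 1))

    def __post_init__(self) -> None:
        if not 0.0 <= self.snack_probability <= 1.0:
            raise ValueError("snack_probability must be in [0, 1]")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.n_patients_per_group < 1:
            raise ValueError("n_patients_per_group must be >= 1")
        if len(self.meal_pivot_times) != 3 or len(self.snack_pivot_times) != 3:
            raise ValueError("exactly 3 meal and 3 snack slots per day")
        if len(self.meal_size_pivot_g) != 3 or len(self.snack_size_pivot_g) != 3:
            raise ValueError("need one size pivot per meal/snack slot")
        if min(self.meal_size_pivot_g) <= 0 or min(self.snack_size_pivot_g) <= 0:
            raise ValueError("all size pivots must be > 0")
        if self.time_jitter_min < 0 or not 0 <= self.size_jitter_frac < 1:
            raise ValueError("invalid jitter settings")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be >= 0")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MealEvent:
    """A single carbohydrate intake (meal or snack)."""

    timestamp: dt.datetime
    carbs_g: float
    is_snack: bool

    def __post_init__(self) -> None:
        if self.carbs_g <= 0:
            raise ValueError("carbs_g must be > 0")


@dataclass(frozen=True)
class VirtualPatientParams:
    """Per-patient metabolic parameters of the two-compartment model.

    basal_glucose        mg/dL    equilibrium glucose with no meals
    insulin_sensitivity  unitless scales the insulin-action drag
    carb_response_gain   mg/dL/g  glucose rise per gram of absorbed carbs
    meal_absorption_tau  minutes  gut absorption time constant
    clearance_rate       1/min    relaxation rate toward basal
    """

    patient_id: str
    age_group: str
    basal_glucose: float
    insulin_sensitivity: float
    carb_response_gain: float
    meal_absorption_tau: float
    clearance_rate: float

    def __post_init__(self) -> None:
        if not 60.0 <= self.basal_glucose <= 200.0:
            raise ValueError("basal_glucose must be in [60, 200] mg/dL")
        for name in ("insulin_sensitivity", "carb_response_gain",
                     "meal_absorption_tau", "clearance_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class RawTrace:
    """Minute-resolution simulated trace for one patient."""

    patient_id: str
    timestamps: pd.DatetimeIndex
    smoothed_glucose: np.ndarray
    noisy_glucose: np.ndarray
    meal_events: tuple[MealEvent, ...]

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        if len(self.smoothed_glucose) != n or len(self.noisy_glucose) != n:
            raise ValueError("glucose series must match the timestamp grid")


# Age-group parameter ranges (low, high) for uniform draws.  Children get a
# higher carb response and slower clearance than adults (wider excursions),
# adolescents sit in between.  Chosen so the default-seed cohort shows a
# realistic class mix: most time in range, roughly a quarter to a third
# above 180 mg/dL, and a few percent below 70 mg/dL.
AGE_GROUP_PARAM_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "adults": {
        "basal_glucose": (110.0, 145.0),
        "insulin_sensitivity": (0.90, 1.20),
        "carb_response_gain": (5.5, 7.0),
        "meal_absorption_tau": (35.0, 45.0),
        "clearance_rate": (0.013, 0.020),
    },
    "adolescents": {
        "basal_glucose": (115.0, 150.0),
        "insulin_sensitivity": (0.95, 1.25),
        "carb_response_gain": (6.0, 8.0),
        "meal_absorption_tau": (35.0, 50.0),
        "clearance_rate": (0.011, 0.017),
    },
    "children": {
        "basal_glucose": (115.0, 155.0),
        "insulin_sensitivity": (1.00, 1.35),
        "carb_response_gain": (7.0, 9.5),
        "meal_absorption_tau": (30.0, 45.0),
        "clearance_rate": (0.010, 0.015),
    },
}
# Groups not named above fall back to this range set.
_DEFAULT_PARAM_RANGES = AGE_GROUP_PARAM_RANGES["adolescents"]


def generate_meal_schedule(config: SimConfig, patient_seed) -> list[MealEvent]:
    """Randomized meal/snack schedule for one patient.

    Per day: exactly three meals, and each of three snack slots is taken
    independently with ``config.snack_probability``.  Times are jittered
    uniformly within +/- ``time_jitter_min`` minutes of the slot pivot and
    sizes within +/- ``size_jitter_frac`` of the size pivot.  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(patient_seed)
    events: list[MealEvent] = []
    meal_minutes = [_parse_clock(s) for s in config.meal_pivot_times]
    snack_minutes = [_parse_clock(s) for s in config.snack_pivot_times]
    for day in range(config.n_days):
        day_start = dt.datetime.combine(
            config.start_date + dt.timedelta(days=day), dt.time()
        )
        for pivot_min, pivot_g in zip(meal_minutes, config.meal_size_pivot_g):
            events.append(_draw_event(rng, config, day_start, pivot_min, pivot_g, False))
        for pivot_min, pivot_g in zip(snack_minutes, config.snack_size_pivot_g):
            take = rng.random() < config.snack_probability
            if take:
                events.append(_draw_event(rng, config, day_start, pivot_min, pivot_g, True))
    events.sort(key=lambda e: e.timestamp)
    return events


def _draw_event(rng, config, day_start, pivot_min, pivot_g, is_snack) -> MealEvent:
    jitter = rng.uniform(-config.time_jitter_min, config.time_jitter_min)
    minute = int(round(pivot_min + jitter))
    minute = min(max(minute, 0), 24 * 60 - 1)  # keep the event inside its day
    size = pivot_g * (1.0 + rng.uniform(-config.size_jitter_frac, config.size_jitter_frac))
    return MealEvent(day_start + dt.timedelta(minutes=minute), float(size), is_snack)


def simulate_glucose(
    params: VirtualPatientParams,
    schedule: list[MealEvent],
    config: SimConfig,
    seed,
) -> RawTrace:
    """Integrate the two-compartment model on a 1-min grid.

    Gut carbohydrate mass Q is absorbed with first-order kinetics (time
    constant ``meal_absorption_tau``) and raises glucose via
    ``carb_response_gain``; an insulin-action compartment X, loaded in
    proportion to each meal and cleared three times slower than the gut,
    drags glucose down scaled by ``insulin_sensitivity``; glucose also
    relaxes toward ``basal_glucose`` at ``clearance_rate``.  Sensor noise
    is i.i.d. Gaussian added to the smoothed trajectory.  Deterministic
    given ``seed``.
    """
    if config.n_days < 1:
        raise ValueError("simulation must span at least one day")
    n_min = config.n_days * 24 * 60
    start = dt.datetime.combine(config.start_date, dt.time())
    timestamps = pd.date_range(start, periods=n_min, freq="min")
    end = timestamps[-1]
    for ev in schedule:
        if not (start <= ev.timestamp <= end):
            raise ValueError(f"meal event {ev.timestamp} outside simulated range")

    # carb impulses on the minute grid
    carb_in = np.zeros(n_min)
    for ev in schedule:
        idx = int((ev.timestamp - start).total_seconds() // 60)
        carb_in[idx] += ev.carbs_g

    tau_m = params.meal_absorption_tau
    tau_i = _INSULIN_TAU_FACTOR * tau_m
    k = params.clearance_rate
    gain = params.carb_response_gain

    smoothed = np.empty(n_min)
    g = params.basal_glucose
    q = 0.0  # gut carb mass, grams
    x = 0.0  # insulin action, gram-equivalents
    for t in range(n_min):
        q += carb_in[t]
        x += carb_in[t]
        absorb = q / tau_m          # g/min reaching plasma
        ins = x / tau_i             # insulin-action flux
        dg = gain * absorb - params.insulin_sensitivity * gain * ins - k * (g - params.basal_glucose)
        q -= absorb
        x -= ins
        g = min(max(g + dg, GLUCOSE_FLOOR), GLUCOSE_CEIL)
        smoothed[t] = g

    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, config.sensor_noise_sd, size=n_min) if config.sensor_noise_sd > 0 else np.zeros(n_min)
    noisy = np.clip(smoothed + noise, GLUCOSE_FLOOR, GLUCOSE_CEIL)
    return RawTrace(params.patient_id, timestamps, smoothed, noisy, tuple(schedule))


def _draw_patient_params(rng, patient_id: str, age_group: str) -> VirtualPatientParams:
    ranges = AGE_GROUP_PARAM_RANGES.get(age_group, _DEFAULT_PARAM_RANGES)
    draws = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in ranges.items()}
    return VirtualPatientParams(patient_id=patient_id, age_group=age_group, **draws)


def patient_seed_sequence(master_seed: int, group_index: int, patient_index: int) -> np.random.SeedSequence:
    """Stable per-patient seed stream.

    Keyed on (master_seed, group, patient) so adding patients or groups
    never perturbs the streams of existing ones.
    """
    return np.random.SeedSequence(master_seed, spawn_key=(group_index, patient_index))


def generate_cohort(config: SimConfig) -> list[RawTrace]:
    """Simulate the full cohort: ``n_patients_per_group`` per age group."""
    traces: list[RawTrace] = []
    for g_idx, group in enumerate(config.age_groups):
        for p_idx in range(config.n_patients_per_group):
            ss = patient_seed_sequence(config.master_seed, g_idx, p_idx)
            param_seed, sched_seed, noise_seed = ss.spawn(3)
            patient_id = f"{group}_{p_idx + 1:02d}"
            params = _draw_patient_params(np.random.default_rng(param_seed), patient_id, group)
            schedule = generate_meal_schedule(config, sched_seed)
            traces.append(simulate_glucose(params, schedule, config, noise_seed))
    return traces


def write_dataset(traces: list[RawTrace], path) -> None:
    """Write traces as the study-schema CSV: one row per simulated minute.

    ``insulin_u`` is left empty (the model folds insulin action into the
    glucose dynamics); ``cho_g`` carries the carbs of any meal event that
    falls in that minute, else 0.
    """
    if not traces:
        raise ValueError("no traces to write")
    frames = []
    for tr in traces:
        cho = np.zeros(len(tr.timestamps))
        start = tr.timestamps[0]
        for ev in tr.meal_events:
            idx = int((ev.timestamp - start).total_seconds() // 60)
            cho[idx] += ev.carbs_g
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": tr.patient_id,
                    "timestamp": tr.timestamps.strftime("%Y-%m-%dT%H:%M"),
                    "cgm_mg_dl": np.round(tr.noisy_glucose, 2),
                    "insulin_u": "",
                    "cho_g": np.round(cho, 2),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
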