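"""End-to-end orchestration: simulate -> preprocess -> featurize -> train ->
evaluate -> report, for every requested model and horizon.

One :class:`RunConfig` (optionally loaded from YAML) fully determines a
run.  A single master seed fans out into named substreams for the
simulator and each model fit, so every stage — and every individual
patient — is reproducible in isolation.  Each stage reads and writes plain
CSV/JSON, so the CLI can also run stages individually on intermediate
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import glycast
from glycast.evaluate import aggregate, confusion_matrix, report, scores
from glycast.features import FeatureSpec, build_feature_matrix
from glycast.models import (
    ArimaSpec,
    ForecastTask,
    LogisticSpec,
    LstmSpec,
    fit_arima,
    fit_logistic,
    fit_lstm,
)
from glycast.preprocess import GlucoseSeries, SplitSpec, clean_and_resample, read_dataset, split_series
from glycast.simulate import SimConfig, generate_cohort, write_dataset

__all__ = ["RunConfig", "run_pipeline", "prepare_series", "run_model", "HORIZON_LABELS"]

log = logging.getLogger(__name__)

MODEL_NAMES = ("arima", "logistic", "lstm")
HORIZON_LABELS = {1: "15min", 4: "1h"}


def derive_seed(master_seed: int, *key) -> int:
    """Stable named substream seed (< 2**31) from the master seed."""
    digest = hashlib.sha256("/".join(str(k) for k in key).encode()).digest()
    sub = int.from_bytes(digest[:4], "big")
    ss = np.random.SeedSequence(master_seed, spawn_key=(sub,))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one comparative run."""

    input_csv: str | None = None  # None -> simulate a cohort first
    sim: SimConfig = field(default_factory=SimConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    features: FeatureSpec = field(default_factory=FeatureSpec)
    arima: ArimaSpec = field(default_factory=ArimaSpec)
    logistic: LogisticSpec = field(default_factory=LogisticSpec)
    lstm: LstmSpec = field(default_factory=LstmSpec)
    models: tuple[str, ...] = MODEL_NAMES
    horizons: tuple[int, ...] = (1, 4)
    out_dir: str = "glycast_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if set(self.models) - set(MODEL_NAMES):
            raise ValueError(f"models must be among {MODEL_NAMES}")
        if set(self.horizons) - set(HORIZON_LABELS):
            raise ValueError("horizons must be among {1, 4} grid steps")
        for h in self.horizons:
            if h not in self.features.horizons_steps:
                raise ValueError(f"horizon {h} missing from features.horizons_steps")

    # -- YAML round trip -------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (("sim", SimConfig), ("split", SplitSpec), ("features", FeatureSpec),
                         ("arima", ArimaSpec), ("logistic", LogisticSpec), ("lstm", LstmSpec)):
            if key in kwargs and isinstance(kwargs[key], dict):
                d = dict(kwargs[key])
                for f_ in dataclasses.fields(sub):
                    if f_.name in d and isinstance(d[f_.name], list):
                        d[f_.name] = tuple(d[f_.name])
                if key == "sim" and "start_date" in d and isinstance(d["start_date"], str):
                    d["start_date"] = pd.Timestamp(d["start_date"]).date()
                kwargs[key] = sub(**d)
        for key in ("models", "horizons"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["start_date"] = str(d["sim"]["start_date"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


# -- stages ---------------------------------------------------------------

def simulate_stage(config: RunConfig, out_path) -> Path:
    """Generate the virtual cohort and write the schema CSV."""
    sim = config.sim.with_(master_seed=derive_seed(config.seed, "simulate"))
    traces = generate_cohort(sim)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    write_dataset(traces, out_path)
    log.info("simulated %d traces -> %s", len(traces), out_path)
    return out_path


def prepare_series(config: RunConfig, dataset_path=None) -> dict[str, GlucoseSeries]:
    """Read (or simulate) the dataset and clean/resample every patient."""
    if dataset_path is None:
        if config.input_csv is not None:
            dataset_path = config.input_csv
        else:
            dataset_path = Path(config.out_dir) / "dataset.csv"
            simulate_stage(config, dataset_path)
    records = read_dataset(dataset_path)
    out = {}
    for pid, rec in records.items():
        series = clean_and_resample(rec, pid)
        if series is not None:
            out[pid] = series
    if not out:
        raise RuntimeError("no usable patients after preprocessing")
    return out


def run_model(
    model_name: str,
    horizon_steps: int,
    series_by_patient: dict[str, GlucoseSeries],
    config: RunConfig,
) -> dict[str, list]:
    """Fit and roll out one model at one horizon for every patient.

    Returns per-patient lists of ClassPrediction.  Patients whose data
    cannot support the fit (too short, single-class training target) are
    skipped with a warning.
    """
    task = ForecastTask(horizon_steps=horizon_steps)
    preds_by_patient: dict[str, list] = {}
    for pid, series in series_by_patient.items():
        try:
            train, test = split_series(series, config.split)
            if model_name == "arima":
                model = fit_arima(train, task, config.arima)
                preds = model.predict_classes(series)
            else:
                frame_in = build_feature_matrix(train, config.features, horizon_steps)
                frame_out = build_feature_matrix(test, config.features, horizon_steps)
                frame_in = frame_in.drop(columns="patient_id")
                frame_out = frame_out.drop(columns="patient_id")
                if model_name == "logistic":
                    model = fit_logistic(frame_in, task, config.logistic)
                else:
                    lstm_spec = dataclasses.replace(
                        config.lstm, seed=derive_seed(config.seed, "lstm", pid, horizon_steps)
                    )
                    model = fit_lstm(frame_in, task, lstm_spec)
                preds = model.predict_classes(frame_out)
        except (ValueError, RuntimeError) as exc:
            log.warning("%s/%s h=%d skipped: %s", model_name, pid, horizon_steps, exc)
            continue
        if preds:
            preds_by_patient[pid] = preds
    return preds_by_patient


def predictions_to_frame(preds_by_patient: dict[str, list]) -> pd.DataFrame:
    rows = []
    for pid, preds in preds_by_patient.items():
        for p in preds:
            rows.append({
                "patient_id": pid,
                "timestamp": p.timestamp,
                "true_class": p.true_class,
                "predicted_class": p.predicted_class,
            })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every requested model x horizon combination and report.

    Writes, under ``config.out_dir``: the simulated dataset (when no input
    CSV is given), per-model/horizon prediction CSVs, per-patient score
    JSON, aggregated confusion matrices, the comparative score grid, and a
    manifest recording the config hash, seed and library versions.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series_by_patient = prepare_series(config)
    log.info("prepared %d patients", len(series_by_patient))

    results: dict[str, dict] = {}
    per_patient_scores: dict = {}
    for model_name in config.models:
        results[model_name] = {}
        for h in config.horizons:
            label = HORIZON_LABELS[h]
            stage = f"{model_name}/{label}"
            try:
                preds = run_model(model_name, h, series_by_patient, config)
            except Exception as exc:
                raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
            if not preds:
                log.warning("stage '%s' produced no predictions", stage)
                results[model_name][label] = None
                continue
            predictions_to_frame(preds).to_csv(
                out_dir / f"predictions_{model_name}_{label}.csv", index=False
            )
            matrices = {pid: confusion_matrix(p) for pid, p in preds.items()}
            per_patient_scores[stage] = {
                pid: scores(cm) for pid, cm in matrices.items()
            }
            results[model_name][label] = aggregate(list(matrices.values()))

    score_grid = report(results, out_dir)
    (out_dir / "per_patient_scores.json").write_text(
        json.dumps(per_patient_scores, indent=2, sort_keys=True)
    )
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "glycast": glycast.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return score_grid
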