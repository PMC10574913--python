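"""Shared fit/predict contract for the three forecasting model families."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from glycast.features import CLASS_ORDER

__all__ = ["ForecastTask", "ClassPrediction", "argmax_class", "feature_columns"]

#: Grid step of the working CGM series, minutes.
GRID_STEP_MIN = 15


@dataclass(frozen=True)
class ForecastTask:
    """A forecast horizon, in steps of the 15-min grid (1 step or 4)."""

    horizon_steps: int

    def __post_init__(self) -> None:
        if self.horizon_steps not in (1, 4):
            raise ValueError("horizon_steps must be 1 (15 min) or 4 (1 h)")

    @property
    def horizon_minutes(self) -> int:
        return GRID_STEP_MIN * self.horizon_steps


@dataclass(frozen=True)
class ClassPrediction:
    """One out-of-sample prediction: true vs predicted glycemia class.

    ``class_probabilities`` is a 3-vector over (hypo, norm, hyper) for the
    probabilistic models and ``None`` for ARIMA, whose class comes from a
    point forecast of the glucose level.
    """

    timestamp: pd.Timestamp
    true_class: int
    predicted_class: int
    class_probabilities: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = self.class_probabilities
        if p is not None:
            p = np.asarray(p, dtype=float)
            if p.shape != (3,) or np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
                raise ValueError("class_probabilities must be a 3-vector summing to 1")


def argmax_class(probabilities: np.ndarray) -> int:
    """Most probable class; ties break toward the lower class (hypo first)."""
    return CLASS_ORDER[int(np.argmax(probabilities))]


def feature_columns(frame: pd.DataFrame) -> list[str]:
    """Predictor columns of a feature frame (everything but id and target)."""
    return [c for c in frame.columns if c not in ("patient_id", "target")]
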