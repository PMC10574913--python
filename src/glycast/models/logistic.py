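"""Multinomial logistic regression on the engineered CGM features."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from glycast.features import CLASS_ORDER
from glycast.models.base import ClassPrediction, ForecastTask, argmax_class, feature_columns

__all__ = ["LogisticSpec", "LogisticForecaster", "fit_logistic"]


@dataclass(frozen=True)
class LogisticSpec:
    """Multinomial logistic regression settings.

    ``regularization_strength`` is the L2 penalty weight (the inverse of
    scikit-learn's C); ``class_weighting='balanced'`` reweights samples
    inversely to class frequency, which matters for the rare hypo class.
    """

    regularization_strength: float = 1.0
    class_weighting: str = "balanced"
    max_iterations: int = 1000

    def __post_init__(self) -> None:
        if self.regularization_strength <= 0:
            raise ValueError("regularization_strength must be > 0")
        if self.class_weighting not in ("none", "balanced"):
            raise ValueError("class_weighting must be 'none' or 'balanced'")


@dataclass
class LogisticForecaster:
    """Fitted multinomial model plus the in-sample standardization."""

    task: ForecastTask
    spec: LogisticSpec
    columns: list[str]
    scaler: StandardScaler = field(repr=False)
    estimator: LogisticRegression = field(repr=False)

    def predict_proba(self, frame: pd.DataFrame) -> np.ndarray:
        """Probabilities over the fixed (hypo, norm, hyper) class set.

        Classes absent from the training data get probability 0 so the
        output is always a full 3-column matrix.
        """
        cols = feature_columns(frame)
        if cols != self.columns:
            raise ValueError("feature columns do not match the training frame")
        if not len(frame):
            return np.zeros((0, 3))
        x = self.scaler.transform(frame[self.columns].to_numpy(dtype=float))
        raw = self.estimator.predict_proba(x)
        out = np.zeros((len(frame), 3))
        for j, cls in enumerate(self.estimator.classes_):
            out[:, CLASS_ORDER.index(int(cls))] = raw[:, j]
        return out

    def predict_classes(self, frame: pd.DataFrame) -> list[ClassPrediction]:
        """One prediction per row of an out-of-sample feature frame."""
        proba = self.predict_proba(frame)
        preds = []
        for ts, true_cls, p in zip(frame.index, frame["target"].to_numpy(), proba):
            preds.append(ClassPrediction(
                timestamp=ts,
                true_class=int(true_cls),
                predicted_class=argmax_class(p),
                class_probabilities=p,
            ))
        return preds


def fit_logistic(frame: pd.DataFrame, task: ForecastTask, spec: LogisticSpec | None = None) -> LogisticForecaster:
    """Fit the multinomial model on an in-sample feature frame.

    Features are z-scored with in-sample statistics; the scaler travels
    with the model so out-of-sample data is transformed identically.
    """
    spec = spec or LogisticSpec()
    if not len(frame):
        raise ValueError("empty in-sample feature frame")
    y = frame["target"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError(
            "in-sample target has a single class; use a different split or seed"
        )
    cols = feature_columns(frame)
    scaler = StandardScaler().fit(frame[cols].to_numpy(dtype=float))
    est = LogisticRegression(
        C=1.0 / spec.regularization_strength,
        class_weight=None if spec.class_weighting == "none" else "balanced",
        max_iter=spec.max_iterations,
    )
    est.fit(scaler.transform(frame[cols].to_numpy(dtype=float)), y)
    return LogisticForecaster(task=task, spec=spec, columns=cols, scaler=scaler, estimator=est)
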