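"""LSTM glycemia-class forecasting on the engineered feature sequences.

Each feature-frame row is turned into a sequence of ``sequence_length``
consecutive steps of the *unlagged* feature vector, reconstructed from the
row's lag columns (lag k of feature f is f at t-k), so the recurrent input
carries exactly the information of "features with lags up to 12" in its
natural sequential form.  A flat mode that feeds the whole lagged row as a
single step is available for parity with the logistic route.

The network itself is the small numpy LSTM in :mod:`glycast.models._rnn`:
one layer of 32 units by default, Adam, weighted cross-entropy with
optional balanced class weights, early stopping on a chronological tail of
the in-sample sequences.  Deliberately small so training is deterministic
and fast on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from glycast.features import CLASS_ORDER
from glycast.models._rnn import AdamOptimizer, LstmNetwork, weighted_cross_entropy
from glycast.models.base import ClassPrediction, ForecastTask, argmax_class, feature_columns

__all__ = ["LstmSpec", "LstmForecaster", "fit_lstm"]

#: Fraction of in-sample sequences (chronological tail) held out for
#: early stopping.
VALIDATION_FRACTION = 0.15


@dataclass(frozen=True)
class LstmSpec:
    """LSTM training configuration.

    sequence_length  steps of the unlagged feature vector per sequence
    hidden_units     LSTM state size
    layers           stacked LSTM layers
    epochs           maximum training epochs
    learning_rate    Adam step size
    batch_size       minibatch size
    class_weighting  'balanced' reweights the rare hypo class
    seed             controls initialization and batch shuffling
    early_stop_patience  epochs without validation improvement before stop
    input_mode       'sequence' (default) or 'flat' (whole lagged row,
                     single step)
    """

    sequence_length: int = 12
    hidden_units: int = 32
    layers: int = 1
    epochs: int = 40
    learning_rate: float = 3e-3
    batch_size: int = 64
    class_weighting: str = "balanced"
    seed: int = 0
    early_stop_patience: int = 5
    input_mode: str = "sequence"

    def __post_init__(self) -> None:
        if self.sequence_length < 1 or self.hidden_units < 1 or self.layers < 1:
            raise ValueError("sequence_length, hidden_units and layers must be >= 1")
        if self.class_weighting not in ("none", "balanced"):
            raise ValueError("class_weighting must be 'none' or 'balanced'")
        if self.input_mode not in ("sequence", "flat"):
            raise ValueError("input_mode must be 'sequence' or 'flat'")


def _base_columns(cols: list[str]) -> list[str]:
    return [c for c in cols if "_lag" not in c]


def _sequence_tensor(frame: pd.DataFrame, spec: LstmSpec, columns: list[str],
                     mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """(rows, sequence_length, features) tensor from a feature frame.

    Step s (oldest first) of row t is the unlagged feature vector at
    t - (sequence_length - 1 - s), read from the lag columns; features are
    z-scored with the supplied in-sample statistics.
    """
    if spec.input_mode == "flat":
        x = frame[columns].to_numpy(dtype=float)
        return ((x - mean) / sd)[:, None, :]
    base = _base_columns(columns)
    max_lag_needed = spec.sequence_length - 1
    available = {int(c.rsplit("_lag", 1)[1]) for c in columns if "_lag" in c}
    if max_lag_needed > 0 and not set(range(1, max_lag_needed + 1)) <= available:
        raise ValueError(
            f"sequence_length {spec.sequence_length} needs lags up to "
            f"{max_lag_needed} in the feature frame"
        )
    T = spec.sequence_length
    out = np.empty((len(frame), T, len(base)))
    for s in range(T):
        lag = T - 1 - s
        names = base if lag == 0 else [f"{c}_lag{lag}" for c in base]
        out[:, s, :] = frame[names].to_numpy(dtype=float)
    return (out - mean) / sd


@dataclass
class LstmForecaster:
    """Trained LSTM plus the preprocessing needed to replay it."""

    task: ForecastTask
    spec: LstmSpec
    columns: list[str]
    mean: np.ndarray = field(repr=False)
    sd: np.ndarray = field(repr=False)
    network: LstmNetwork = field(repr=False)
    history: list[dict] = field(default_factory=list, repr=False)

    def predict_proba(self, frame: pd.DataFrame) -> np.ndarray:
        cols = feature_columns(frame)
        if cols != self.columns:
            raise ValueError("feature columns do not match the training frame")
        if not len(frame):
            return np.zeros((0, 3))
        x = _sequence_tensor(frame, self.spec, self.columns, self.mean, self.sd)
        return self.network.predict_proba(x)

    def predict_classes(self, frame: pd.DataFrame) -> list[ClassPrediction]:
        proba = self.predict_proba(frame)
        return [
            ClassPrediction(
                timestamp=ts,
                true_class=int(true_cls),
                predicted_class=argmax_class(p),
                class_probabilities=p,
            )
            for ts, true_cls, p in zip(frame.index, frame["target"].to_numpy(), proba)
        ]


def _class_weights(y: np.ndarray, mode: str) -> np.ndarray:
    """Per-sample weights; 'balanced' uses n / (k * count(class))."""
    if mode == "none":
        return np.ones(len(y))
    classes, counts = np.unique(y, return_counts=True)
    w = {c: len(y) / (len(classes) * n) for c, n in zip(classes, counts)}
    return np.array([w[v] for v in y])


def fit_lstm(frame: pd.DataFrame, task: ForecastTask, spec: LstmSpec | None = None) -> LstmForecaster:
    """Train the LSTM on an in-sample feature frame.

    Standardization statistics come from the in-sample frame only.  The
    chronological tail of the sequences is held out for early stopping;
    the parameters with the best validation loss are restored at the end.
    All randomness is driven by ``spec.seed``.
    """
    spec = spec or LstmSpec()
    if not len(frame):
        raise ValueError("empty in-sample feature frame")
    cols = feature_columns(frame)
    y_signed = frame["target"].to_numpy(dtype=int)
    y = np.array([CLASS_ORDER.index(v) for v in y_signed])

    if spec.input_mode == "flat":
        stats_cols = cols
    else:
        stats_cols = _base_columns(cols)
    raw = frame[stats_cols].to_numpy(dtype=float)
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)
    sd[sd == 0] = 1.0

    x = _sequence_tensor(frame, spec, cols, mean, sd)
    n = len(x)
    if n < spec.batch_size:
        raise ValueError(f"only {n} sequences, need at least batch_size={spec.batch_size}")

    n_val = max(1, int(round(n * VALIDATION_FRACTION)))
    x_tr, y_tr = x[: n - n_val], y[: n - n_val]
    x_val, y_val = x[n - n_val :], y[n - n_val :]
    w_tr = _class_weights(y_tr, spec.class_weighting)
    w_val = _class_weights(y_val, spec.class_weighting)

    rng = np.random.default_rng(spec.seed)
    net = LstmNetwork(x.shape[2], spec.hidden_units, spec.layers, 3, rng)
    opt = AdamOptimizer(net.params, lr=spec.learning_rate)

    best_state = net.get_state()
    best_val = np.inf
    patience_left = spec.early_stop_patience
    history: list[dict] = []
    for epoch in range(spec.epochs):
        order = rng.permutation(len(x_tr))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(x_tr), spec.batch_size):
            idx = order[start : start + spec.batch_size]
            probs, cache = net.forward(x_tr[idx])
            grads = net.backward(cache, y_tr[idx], w_tr[idx])
            opt.step(net.params, grads)
            epoch_loss += weighted_cross_entropy(probs, y_tr[idx], w_tr[idx])
            n_batches += 1
        val_probs = net.predict_proba(x_val)
        val_loss = weighted_cross_entropy(val_probs, y_val, w_val)
        history.append({"epoch": epoch, "train_loss": epoch_loss / n_batches, "val_loss": val_loss})
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = net.get_state()
            patience_left = spec.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    net.set_state(best_state)
    return LstmForecaster(task=task, spec=spec, columns=cols, mean=mean, sd=sd,
                          network=net, history=history)
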