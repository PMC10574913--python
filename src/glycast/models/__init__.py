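"""Forecast models: ARIMA, multinomial logistic regression, LSTM.

All three expose the same contract: a ``fit_*`` function that sees only
in-sample data, and ``predict_classes`` producing one
:class:`~glycast.models.base.ClassPrediction` per usable out-of-sample
time point.
"""

from glycast.models.arima import ArimaForecaster, ArimaSpec, fit_arima
from glycast.models.base import ClassPrediction, ForecastTask
from glycast.models.logistic import LogisticForecaster, LogisticSpec, fit_logistic
from glycast.models.lstm import LstmForecaster, LstmSpec, fit_lstm

__all__ = [
    "ForecastTask",
    "ClassPrediction",
    "ArimaSpec",
    "ArimaForecaster",
    "fit_arima",
    "LogisticSpec",
    "LogisticForecaster",
    "fit_logistic",
    "LstmSpec",
    "LstmForecaster",
    "fit_lstm",
    "predict_classes",
]


def predict_classes(model, data, task: ForecastTask | None = None):
    """Dispatch to the fitted model's own ``predict_classes``.

    ``data`` is a :class:`~glycast.preprocess.GlucoseSeries` (full observed
    history) for ARIMA and an out-of-sample feature frame for the logistic
    and LSTM models.  ``task``, when given, must match the model's horizon.
    """
    if task is not None and task != model.task:
        raise ValueError(f"model was fitted for {model.task}, asked for {task}")
    return model.predict_classes(data)
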