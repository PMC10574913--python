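"""ARIMA glycemia-class forecasting.

The ARIMA route works on the raw CGM level series (d = 1, so the model
effectively forecasts CGM differences), converts point forecasts back to
levels and maps them through the glycemia-class thresholds.  For the 1-h
horizon the series is, by default, resampled to a 60-min grid and forecast
one step ahead; the alternative of iterating four 15-min steps is available
behind ``resample_for_1h=False``.

Out-of-sample evaluation is rolling with frozen parameters: the model is
estimated once on the in-sample window, then each out-of-sample origin
re-uses those parameters with the filter state updated by the observed
history (no refitting).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.statespace.sarimax import SARIMAX

from glycast.features import glycemia_class
from glycast.models.base import ClassPrediction, ForecastTask
from glycast.preprocess import GlucoseSeries

__all__ = ["ArimaSpec", "ArimaForecaster", "fit_arima"]

log = logging.getLogger(__name__)

MIN_FIT_POINTS = 100


@dataclass(frozen=True)
class ArimaSpec:
    """ARIMA configuration.

    ``order=None`` selects (p, 1, q) by lowest AIC over the grid; a fixed
    ``order`` skips selection.  ``resample_for_1h`` switches the 1-h task
    between hourly resampling (default) and iterated 15-min forecasting.
    """

    order: tuple[int, int, int] | None = None
    p_grid: tuple[int, ...] = (0, 1, 2, 3)
    q_grid: tuple[int, ...] = (0, 1, 2, 3)
    d: int = 1
    resample_for_1h: bool = True

    def __post_init__(self) -> None:
        if self.d not in (0, 1):
            raise ValueError("d must be 0 or 1")
        if self.order is not None:
            p, d, q = self.order
            if d not in (0, 1) or p > 3 or q > 3 or p < 0 or q < 0:
                raise ValueError("order limited to p,q <= 3 and d in {0,1}")


def _working_series(series: GlucoseSeries, task: ForecastTask, spec: ArimaSpec) -> pd.Series:
    """Level series at the model's working frequency, NaN across gaps.

    For the 1-h task with resampling, every 4th grid point is kept so one
    model step spans one hour.
    """
    full = pd.Series(np.nan, index=pd.date_range(
        series.timestamps[0], series.timestamps[-1], freq=f"{series.grid_min}min"))
    full.loc[series.timestamps] = series.cgm
    if task.horizon_steps == 4 and spec.resample_for_1h:
        full = full.iloc[::4]
    return full


@dataclass
class ArimaForecaster:
    """A fitted ARIMA model plus everything needed for rolling prediction."""

    patient_id: str
    task: ForecastTask
    spec: ArimaSpec
    order: tuple[int, int, int]
    results: object = field(repr=False)
    in_sample_end: pd.Timestamp = None

    def predict_classes(self, context: GlucoseSeries) -> list[ClassPrediction]:
        """Rolling out-of-sample class predictions.

        ``context`` must contain the full observed history (in-sample and
        out-of-sample); predictions are emitted for every out-of-sample
        time whose forecast and observation are both defined.  Parameters
        stay frozen at the in-sample fit; only the filter state advances.
        """
        work = _working_series(context, self.task, self.spec)
        out_mask = work.index > self.in_sample_end
        if not out_mask.any():
            return []
        if self.task.horizon_steps == 4 and not self.spec.resample_for_1h:
            return self._predict_iterated(work, out_mask)
        applied = self.results.apply(endog=work.to_numpy(), refit=False)
        start = int(np.argmax(out_mask))
        pred = applied.get_prediction(start=start, end=len(work) - 1, dynamic=False)
        levels = np.asarray(pred.predicted_mean)
        preds: list[ClassPrediction] = []
        for ts, obs, lev in zip(work.index[start:], work.to_numpy()[start:], levels):
            if not (np.isfinite(obs) and np.isfinite(lev)):
                log.debug("%s: skipped origin at %s (gap)", self.patient_id, ts)
                continue
            preds.append(ClassPrediction(
                timestamp=ts,
                true_class=int(glycemia_class(obs)),
                predicted_class=int(glycemia_class(lev)),
            ))
        return preds

    def _predict_iterated(self, work: pd.Series, out_mask: np.ndarray) -> list[ClassPrediction]:
        """1-h forecasts as four iterated 15-min steps (non-default path)."""
        h = self.task.horizon_steps
        values = work.to_numpy()
        preds: list[ClassPrediction] = []
        first_out = int(np.argmax(out_mask))
        state = self.results.apply(endog=values[:first_out], refit=False)
        for t in range(first_out, len(values)):
            lev = np.asarray(state.forecast(steps=h))[-1]
            target_idx = t + h - 1
            if target_idx < len(values):
                obs = values[target_idx]
                if np.isfinite(obs) and np.isfinite(lev):
                    preds.append(ClassPrediction(
                        timestamp=work.index[target_idx],
                        true_class=int(glycemia_class(obs)),
                        predicted_class=int(glycemia_class(lev)),
                    ))
            state = state.append(values[t : t + 1], refit=False)
        return preds


def _fit_one(endog: np.ndarray, order: tuple[int, int, int]):
    model = SARIMAX(
        endog,
        order=order,
        enforce_stationarity=True,
        enforce_invertibility=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(disp=0)


def fit_arima(in_sample: GlucoseSeries, task: ForecastTask, spec: ArimaSpec | None = None) -> ArimaForecaster:
    """Estimate the ARIMA model on the in-sample series.

    With ``spec.order`` unset, (p, d=1, q) is chosen by lowest AIC over the
    grid; grid cells that fail to converge are skipped.  Raises if the
    working series is shorter than 100 points or no cell converges.
    """
    spec = spec or ArimaSpec()
    work = _working_series(in_sample, task, spec)
    endog = work.to_numpy()
    n_obs = int(np.isfinite(endog).sum())
    if n_obs < MIN_FIT_POINTS:
        raise ValueError(
            f"{in_sample.patient_id}: only {n_obs} points at working frequency, "
            f"need >= {MIN_FIT_POINTS}"
        )
    if spec.order is not None:
        candidates = [spec.order]
    else:
        candidates = [(p, spec.d, q) for p in spec.p_grid for q in spec.q_grid]
    best = None
    for order in candidates:
        try:
            res = _fit_one(endog, order)
        except Exception as exc:  # non-convergence or numerical failure
            log.debug("%s: ARIMA%s failed: %s", in_sample.patient_id, order, exc)
            continue
        if not np.isfinite(res.aic):
            continue
        if best is None or res.aic < best[0]:
            best = (res.aic, order, res)
    if best is None:
        raise RuntimeError(
            f"{in_sample.patient_id}: no ARIMA order in the grid converged"
        )
    _, order, res = best
    return ArimaForecaster(
        patient_id=in_sample.patient_id,
        task=task,
        spec=spec,
        order=order,
        results=res,
        in_sample_end=work.index[-1],
    )
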