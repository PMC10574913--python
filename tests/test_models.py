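"""Model contracts: ARIMA, multinomial logistic regression, numpy LSTM."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from glycast.features import FeatureSpec, build_feature_matrix, glycemia_class
from glycast.models import (
    ArimaSpec,
    ForecastTask,
    LogisticSpec,
    LstmSpec,
    fit_arima,
    fit_logistic,
    fit_lstm,
    predict_classes,
)
from glycast.models._rnn import LstmNetwork, weighted_cross_entropy
from glycast.models.arima import _working_series
from glycast.preprocess import SplitSpec, split_series
from tests.conftest import make_series


def test_forecast_task_horizon_bookkeeping():
    assert ForecastTask(1).horizon_minutes == 15
    assert ForecastTask(4).horizon_minutes == 60
    with pytest.raises(ValueError):
        ForecastTask(2)


# -- ARIMA ----------------------------------------------------------------


class TestArima:
    def test_white_noise_differences_select_empty_order(self):
        """A pure random walk has white-noise differences: AIC picks
        (0,1,0) and the forecast difference is ~0 (persistence)."""
        rng = np.random.default_rng(8)
        series = make_series(np.clip(150 + np.cumsum(rng.normal(0, 3, 400)), 25, 590))
        model = fit_arima(series, ForecastTask(1), ArimaSpec())
        assert model.order == (0, 1, 0)
        fc = float(np.asarray(model.results.forecast(1))[0])
        assert fc == pytest.approx(series.cgm[-1], abs=1e-6)

    def test_hourly_resampling_for_1h_task(self):
        series = make_series(np.linspace(80, 200, 960))
        work = _working_series(series, ForecastTask(4), ArimaSpec())
        assert len(work) == 240  # 960 quarter-hour points -> hourly
        assert (work.index[1] - work.index[0]) == pd.Timedelta("1h")

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(3)
        series = make_series(np.clip(130 + np.cumsum(rng.normal(0, 4, 300)), 25, 590))
        a = fit_arima(series, ForecastTask(1), ArimaSpec())
        b = fit_arima(series, ForecastTask(1), ArimaSpec())
        assert a.order == b.order
        np.testing.assert_array_equal(a.results.params, b.results.params)

    def test_persistence_forecast_keeps_last_class(self):
        """Near-constant glucose: zero forecast difference, so the
        predicted class equals the class of the last observation."""
        rng = np.random.default_rng(1)
        cgm = np.full(260, 150.0) + rng.normal(0, 0.3, 260)
        series = make_series(cgm)
        train, _ = split_series(series, SplitSpec(0.75))
        model = fit_arima(train, ForecastTask(1), ArimaSpec(order=(0, 1, 0)))
        preds = model.predict_classes(series)
        assert preds, "rolling prediction produced nothing"
        assert all(p.predicted_class == 0 for p in preds)

    def test_class_conversion_commutes_with_threshold_mapping(self):
        """Forecast +90 mg/dL from 100 crosses into hyper exactly as the
        threshold mapping dictates."""
        assert glycemia_class(100.0 + 90.0) == 1
        assert glycemia_class(100.0 + 80.0) == 0  # 180 itself is norm
        rng = np.random.default_rng(2)
        series = make_series(np.clip(120 + np.cumsum(rng.normal(0, 5, 400)), 25, 590))
        train, _ = split_series(series, SplitSpec(0.75))
        model = fit_arima(train, ForecastTask(1), ArimaSpec(order=(1, 1, 1)))
        work = _working_series(series, model.task, model.spec)
        applied = model.results.apply(endog=work.to_numpy(), refit=False)
        start = int(np.argmax(work.index > model.in_sample_end))
        levels = np.asarray(
            applied.get_prediction(start=start, end=len(work) - 1).predicted_mean
        )
        preds = model.predict_classes(series)
        by_ts = {p.timestamp: p.predicted_class for p in preds}
        for ts, level in zip(work.index[start:], levels):
            if ts in by_ts:
                assert by_ts[ts] == glycemia_class(float(level))

    def test_short_series_rejected(self):
        series = make_series(np.full(50, 120.0))
        with pytest.raises(ValueError, match="p1"):
            fit_arima(series, ForecastTask(1), ArimaSpec(order=(0, 1, 0)))


# -- logistic regression --------------------------------------------------


def _synthetic_frame(n=1200, seed=0, p=(0.04, 0.8, 0.16), scale=2.5):
    rng = np.random.default_rng(seed)
    y = rng.choice([-1, 0, 1], size=n, p=list(p))
    idx = pd.date_range("2023-01-01", periods=n, freq="15min")
    return pd.DataFrame(
        {"x1": y * 2.0 + rng.normal(0, scale, n), "x2": rng.normal(0, 1, n), "target": y},
        index=idx,
    )


class TestLogistic:
    def test_separable_frame_near_perfect(self):
        frame = _synthetic_frame(scale=0.01)  # classes essentially separable
        model = fit_logistic(frame, ForecastTask(1))
        preds = model.predict_classes(frame)
        acc = np.mean([p.predicted_class == p.true_class for p in preds])
        assert acc >= 0.99

    def test_balanced_weighting_raises_rare_class_recall(self):
        frame = _synthetic_frame()
        recalls = {}
        for w in ("balanced", "none"):
            model = fit_logistic(frame, ForecastTask(1), LogisticSpec(class_weighting=w))
            preds = model.predict_classes(frame)
            hypo = [p for p in preds if p.true_class == -1]
            recalls[w] = np.mean([p.predicted_class == -1 for p in hypo])
        assert recalls["balanced"] > recalls["none"]

    def test_probabilities_full_simplex(self):
        # training data missing the hypo class entirely
        frame = _synthetic_frame(p=(0.0, 0.8, 0.2))
        model = fit_logistic(frame, ForecastTask(1))
        proba = model.predict_proba(frame)
        assert proba.shape == (len(frame), 3)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert (proba[:, 0] == 0).all()  # unseen class keeps zero mass

    def test_single_class_training_rejected(self):
        frame = _synthetic_frame(p=(0.0, 1.0, 0.0))
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(frame, ForecastTask(1))

    def test_prediction_invariant_to_row_order(self):
        frame = _synthetic_frame()
        model = fit_logistic(frame, ForecastTask(1))
        shuffled = frame.sample(frac=1.0, random_state=1)
        direct = {p.timestamp: p.predicted_class for p in model.predict_classes(frame)}
        mixed = {p.timestamp: p.predicted_class for p in model.predict_classes(shuffled)}
        assert direct == mixed

    def test_column_mismatch_rejected(self):
        frame = _synthetic_frame()
        model = fit_logistic(frame, ForecastTask(1))
        with pytest.raises(ValueError, match="columns"):
            model.predict_classes(frame.rename(columns={"x1": "z1"}))

    def test_empty_out_of_sample_frame(self):
        frame = _synthetic_frame()
        model = fit_logistic(frame, ForecastTask(1))
        assert model.predict_classes(frame.iloc[:0]) == []


# -- LSTM -----------------------------------------------------------------


def test_lstm_backward_matches_numerical_gradient():
    """BPTT gradients agree with central finite differences."""
    rng = np.random.default_rng(0)
    net = LstmNetwork(n_features=3, hidden_units=4, n_layers=2, n_classes=3, rng=rng)
    x = rng.normal(size=(5, 3, 3))
    y = np.array([0, 1, 2, 1, 0])
    w = np.array([1.0, 2.0, 1.0, 0.5, 1.0])

    def loss():
        probs, _ = net.forward(x)
        return weighted_cross_entropy(probs, y, w)

    probs, cache = net.forward(x)
    grads = net.backward(cache, y, w)
    eps = 1e-6
    for name in ("Wx0", "Wh1", "b0", "Wout", "bout"):
        p = net.params[name]
        flat = p.reshape(-1)
        for k in rng.choice(flat.size, size=min(6, flat.size), replace=False):
            orig = flat[k]
            flat[k] = orig + eps
            up = loss()
            flat[k] = orig - eps
            down = loss()
            flat[k] = orig
            num = (up - down) / (2 * eps)
            ana = grads[name].reshape(-1)[k]
            assert ana == pytest.approx(num, rel=1e-4, abs=1e-7), name


@pytest.fixture(scope="module")
def lstm_frames():
    rng = np.random.default_rng(7)
    cgm = np.clip(np.cumsum(rng.normal(0, 6, 500)) + 130, 25, 590)
    series = make_series(cgm)
    frame = build_feature_matrix(series, FeatureSpec(), 1).drop(columns="patient_id")
    return series, frame


class TestLstm:
    def test_training_reproducible_per_seed(self, lstm_frames):
        _, frame = lstm_frames
        spec = LstmSpec(epochs=3, seed=5, hidden_units=8)
        a = fit_lstm(frame, ForecastTask(1), spec)
        b = fit_lstm(frame, ForecastTask(1), spec)
        for k in a.network.params:
            np.testing.assert_array_equal(a.network.params[k], b.network.params[k])
        c = fit_lstm(frame, ForecastTask(1), LstmSpec(epochs=3, seed=6, hidden_units=8))
        assert any(
            not np.array_equal(a.network.params[k], c.network.params[k])
            for k in a.network.params
        )

    def test_horizon_zero_surrogate_is_learnable(self, lstm_frames):
        """With the current class as target the task is readable from the
        input; the network must essentially solve it."""
        series, frame = lstm_frames
        surrogate = frame.copy()
        cur = pd.Series(glycemia_class(series.cgm), index=series.timestamps)
        surrogate["target"] = cur.loc[surrogate.index].to_numpy()
        model = fit_lstm(surrogate, ForecastTask(1), LstmSpec(epochs=40, seed=1))
        preds = model.predict_classes(surrogate)
        acc = np.mean([p.predicted_class == p.true_class for p in preds])
        assert acc >= 0.95

    def test_probabilities_valid_simplex(self, lstm_frames):
        _, frame = lstm_frames
        model = fit_lstm(frame, ForecastTask(1), LstmSpec(epochs=2, seed=0, hidden_units=8))
        proba = model.predict_proba(frame)
        assert (proba >= 0).all()
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_prediction_invariant_to_row_order(self, lstm_frames):
        _, frame = lstm_frames
        model = fit_lstm(frame, ForecastTask(1), LstmSpec(epochs=2, seed=0, hidden_units=8))
        shuffled = frame.sample(frac=1.0, random_state=2)
        direct = {p.timestamp: p.predicted_class for p in model.predict_classes(frame)}
        mixed = {p.timestamp: p.predicted_class for p in model.predict_classes(shuffled)}
        assert direct == mixed

    def test_too_few_sequences_rejected(self, lstm_frames):
        _, frame = lstm_frames
        with pytest.raises(ValueError, match="batch_size"):
            fit_lstm(frame.iloc[:10], ForecastTask(1), LstmSpec(batch_size=64))

    def test_flat_input_mode(self, lstm_frames):
        _, frame = lstm_frames
        spec = LstmSpec(epochs=2, seed=0, hidden_units=8, input_mode="flat")
        model = fit_lstm(frame, ForecastTask(1), spec)
        assert model.predict_proba(frame).shape == (len(frame), 3)


# -- shared dispatch ------------------------------------------------------


def test_predict_classes_dispatch_checks_task(lstm_frames=None):
    frame = _synthetic_frame()
    model = fit_logistic(frame, ForecastTask(1))
    preds = predict_classes(model, frame, ForecastTask(1))
    assert [p.timestamp for p in preds] == list(frame.index)  # 1:1 alignment
    with pytest.raises(ValueError, match="fitted for"):
        predict_classes(model, frame, ForecastTask(4))
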