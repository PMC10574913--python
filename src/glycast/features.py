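"""Rolling-window CGM features, glycemia classes and design matrices.

The feature set derived from a 15-min CGM series:

* first and second differences ``dCGM``, ``d2CGM``;
* rolling min/max over a trailing window of N points and the *range
  oscillator* — the relative position of the current reading inside that
  rolling range, in [0, 1];
* *MAD volatility* — the mean absolute first difference over a trailing
  window of M points;
* *relative speed* — the latest change divided by the previous step's
  volatility (magnitude above 1 flags trend acceleration);
* the three-level glycemia class GC(t): -1 below 70 mg/dL (hypo), +1 above
  180 mg/dL (hyper), 0 otherwise (norm), both thresholds inclusive to norm.

``build_feature_matrix`` assembles all of these at every configured window
size, their lags up to ``max_lag``, and the class ``horizon`` steps ahead
as the prediction target — strictly causal: every value in row t depends
only on readings at or before t, and windows never cross a gap segment
boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from glycast.preprocess import GlucoseSeries

__all__ = [
    "FeatureSpec",
    "HYPO",
    "NORM",
    "HYPER",
    "CLASS_ORDER",
    "CLASS_NAMES",
    "glycemia_class",
    "cgm_differences",
    "rolling_range",
    "range_oscillator",
    "volatility_mad",
    "relative_speed",
    "build_feature_matrix",
    "base_feature_frame",
]

HYPO, NORM, HYPER = -1, 0, 1
#: Fixed class ordering used everywhere: hypo < norm < hyper.
CLASS_ORDER = (HYPO, NORM, HYPER)
CLASS_NAMES = {HYPO: "hypo", NORM: "norm", HYPER: "hyper"}

#: Value of the range oscillator on a flat window (max == min): mid-range
#: rather than missing, so night-time glucose plateaus keep their rows.
FLAT_WINDOW_OSCILLATOR = 0.5


@dataclass(frozen=True)
class FeatureSpec:
    """Window sizes, lag depth and forecast horizons of the feature set.

    Window sizes apply to both the rolling range (N) and the volatility
    window (M); defaults {4, 8, 12} are multiples of four grid steps, i.e.
    one, two and three hours of a 15-min series.  Horizons are in grid
    steps: 1 step = 15 min, 4 steps = 1 h.
    """

    window_sizes: tuple[int, ...] = (4, 8, 12)
    diff_orders: tuple[int, ...] = (1, 2)
    max_lag: int = 12
    horizons_steps: tuple[int, ...] = (1, 4)

    def __post_init__(self) -> None:
        if not self.window_sizes or min(self.window_sizes) < 2:
            raise ValueError("window_sizes must all be >= 2")
        if any(w % 4 for w in self.window_sizes):
            raise ValueError("window sizes must be multiples of 4 (hours of a 15-min grid)")
        if set(self.diff_orders) - {1, 2}:
            raise ValueError("diff_orders must be a subset of {1, 2}")
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if set(self.horizons_steps) - {1, 2, 3, 4}:
            raise ValueError("horizons limited to 1..4 steps (15 min .. 1 h)")


def glycemia_class(cgm_value) -> np.ndarray | int:
    """Map CGM level(s) in mg/dL to the class {-1, 0, +1}.

    Strict thresholds: > 180 is hyper, < 70 is hypo; both boundary values
    70 and 180 are norm.  Accepts scalars or arrays.
    """
    arr = np.asarray(cgm_value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("glycemia_class requires finite CGM values")
    out = np.zeros(arr.shape, dtype=np.int64)
    out[arr > 180.0] = HYPER
    out[arr < 70.0] = HYPO
    if np.ndim(cgm_value) == 0:
        return int(out)
    return out


def cgm_differences(series, order: int = 1) -> pd.Series:
    """Order-1 or order-2 differences of a single-segment CGM series.

    The result is aligned to the input index; the first ``order`` values
    are missing (no predecessors).
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    s = pd.Series(series) if not isinstance(series, pd.Series) else series
    return s.diff().diff() if order == 2 else s.diff()


def rolling_range(series, n: int) -> tuple[pd.Series, pd.Series]:
    """Trailing min and max over the current value and its N-1 predecessors.

    Undefined (missing) for the first N-1 positions.
    """
    if n < 2:
        raise ValueError("window size N must be >= 2")
    s = pd.Series(series) if not isinstance(series, pd.Series) else series
    return s.rolling(n).min(), s.rolling(n).max()


def range_oscillator(series, n: int) -> pd.Series:
    """Relative position of the current value in its trailing N-window range.

    1 at the top of the range, 0 at the bottom; a degenerate flat window
    (max == min) yields ``FLAT_WINDOW_OSCILLATOR`` (0.5).
    """
    s = pd.Series(series) if not isinstance(series, pd.Series) else series
    lo, hi = rolling_range(s, n)
    span = hi - lo
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        osc = (s - lo) / span
    flat = span == 0
    osc[flat] = FLAT_WINDOW_OSCILLATOR
    return osc


def volatility_mad(series, m: int) -> pd.Series:
    """MAD volatility: mean of the last M absolute first differences."""
    if m < 1:
        raise ValueError("window size M must be >= 1")
    s = pd.Series(series) if not isinstance(series, pd.Series) else series
    return s.diff().abs().rolling(m).mean()


def relative_speed(series, m: int) -> pd.Series:
    """Latest change relative to the previous step's MAD volatility.

    RS(t, M) = dCGM(t) / MAD(t-1, M); where the trailing volatility is
    zero the ratio is undefined and returned as missing.
    """
    s = pd.Series(series) if not isinstance(series, pd.Series) else series
    d = s.diff()
    vol_prev = volatility_mad(s, m).shift(1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rs = d / vol_prev
    rs[vol_prev == 0] = np.nan
    return rs


def base_feature_frame(cgm: pd.Series, spec: FeatureSpec) -> pd.DataFrame:
    """All unlagged features of one contiguous CGM segment.

    Column order is fixed; values in row t are functions of cgm[:t+1] only.
    """
    cols: dict[str, pd.Series] = {}
    for order in sorted(spec.diff_orders):
        name = "dCGM" if order == 1 else "d2CGM"
        cols[name] = cgm_differences(cgm, order)
    for n in spec.window_sizes:
        lo, hi = rolling_range(cgm, n)
        cols[f"rmin_{n}"] = lo
        cols[f"rmax_{n}"] = hi
        cols[f"osc_{n}"] = range_oscillator(cgm, n)
    for m in spec.window_sizes:
        cols[f"mad_{m}"] = volatility_mad(cgm, m)
    for m in spec.window_sizes:
        cols[f"rs_{m}"] = relative_speed(cgm, m)
    return pd.DataFrame(cols, index=cgm.index)


def build_feature_matrix(
    series: GlucoseSeries, spec: FeatureSpec, horizon_steps: int
) -> pd.DataFrame:
    """Design matrix + target for one patient and one forecast horizon.

    Columns: every base feature, its lags 1..max_lag (suffix ``_lagK``),
    and the target column ``target`` = GC(t + horizon_steps).  Rows whose
    features, lags or target would cross a segment boundary, or that
    contain any missing value, are dropped.  Returns an empty frame (with
    a warning) when no row survives.
    """
    if horizon_steps not in spec.horizons_steps:
        raise ValueError(f"horizon {horizon_steps} not in spec.horizons_steps")
    pieces = []
    for _seg_id, sl in series.segments():
        cgm = pd.Series(series.cgm[sl], index=series.timestamps[sl])
        base = base_feature_frame(cgm, spec)
        frame = pd.concat(
            [base]
            + [base.shift(lag).add_suffix(f"_lag{lag}") for lag in range(1, spec.max_lag + 1)],
            axis=1,
        )
        gc = pd.Series(glycemia_class(cgm.to_numpy()), index=cgm.index)
        frame["target"] = gc.shift(-horizon_steps)
        frame = frame.dropna()
        if len(frame):
            pieces.append(frame)
    if not pieces:
        warnings.warn(
            f"{series.patient_id}: series too short for warm-up + horizon, empty feature matrix"
        )
        base_cols = list(base_feature_frame(pd.Series([0.0, 1.0]), spec).columns)
        cols = base_cols + [
            f"{c}_lag{k}" for k in range(1, spec.max_lag + 1) for c in base_cols
        ]
        return pd.DataFrame(columns=["patient_id"] + cols + ["target"])
    out = pd.concat(pieces)
    out["target"] = out["target"].astype(np.int64)
    out.insert(0, "patient_id", series.patient_id)
    return out
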