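"""Raw CGM records -> clean 15-min series and chronological splits.

Handles both simulator output and real sensor exports that follow the
``patient_id,timestamp,cgm_mg_dl,insulin_u,cho_g`` schema: drops bad
entries, bins everything to a regular 15-min grid, interpolates short
sensor dropouts, segments the series at long gaps, and cuts each patient's
timeline into chronological in-sample / out-of-sample parts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from glycast.simulate import DATASET_COLUMNS, GLUCOSE_CEIL, GLUCOSE_FLOOR

__all__ = [
    "GlucoseSeries",
    "SplitSpec",
    "SchemaError",
    "read_dataset",
    "clean_and_resample",
    "split_series",
    "write_series_csv",
    "read_series_csv",
]

log = logging.getLogger(__name__)

#: Sensor dropouts up to this long are bridged by linear interpolation;
#: anything longer starts a new segment instead of fabricating data.
MAX_GAP_FILL_MIN = 60

#: Patients contributing fewer usable grid points than this are excluded.
MIN_GRID_POINTS = 16


class SchemaError(ValueError):
    """The input file does not follow the dataset schema."""


@dataclass(frozen=True)
class GlucoseSeries:
    """One patient's CGM trace on a regular 15-min grid.

    ``segment_ids`` marks maximal runs of contiguous 15-min steps; within a
    segment there are no missing values and consecutive timestamps differ
    by exactly the grid step.  Windowed computations downstream must not
    cross segment boundaries.
    """

    patient_id: str
    timestamps: pd.DatetimeIndex
    cgm: np.ndarray
    segment_ids: np.ndarray
    insulin: np.ndarray | None = None
    cho: np.ndarray | None = None
    grid_min: int = 15

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        if len(self.cgm) != n or len(self.segment_ids) != n:
            raise ValueError("cgm/segment_ids must match the timestamp grid")
        if n:
            step = pd.Timedelta(minutes=self.grid_min)
            same_seg = self.segment_ids[1:] == self.segment_ids[:-1]
            diffs = np.asarray(self.timestamps[1:]) - np.asarray(self.timestamps[:-1])
            if np.any(same_seg & (diffs != step.to_numpy())):
                raise ValueError("non-contiguous timestamps inside a segment")
            if np.any(~np.isfinite(self.cgm)):
                raise ValueError("missing cgm inside a segment")

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        d = {"cgm": self.cgm, "segment_id": self.segment_ids}
        if self.insulin is not None:
            d["insulin"] = self.insulin
        if self.cho is not None:
            d["cho"] = self.cho
        return pd.DataFrame(d, index=self.timestamps)

    def segments(self):
        """Yield (segment_id, slice) pairs in chronological order."""
        ids = self.segment_ids
        if not len(ids):
            return
        start = 0
        for i in range(1, len(ids) + 1):
            if i == len(ids) or ids[i] != ids[start]:
                yield int(ids[start]), slice(start, i)
                start = i


@dataclass(frozen=True)
class SplitSpec:
    """Chronological in/out-of-sample split by fraction of grid points."""

    in_sample_fraction: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 < self.in_sample_fraction < 1.0:
            raise ValueError("in_sample_fraction must be in (0, 1)")


def read_dataset(path) -> dict[str, pd.DataFrame]:
    """Read a schema CSV into per-patient, timestamp-sorted frames.

    Rows with unparseable timestamps or glucose values are counted and
    reported via logging; duplicate (patient, timestamp) rows are collapsed
    by the mean of their numeric fields.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    if list(df.columns) != DATASET_COLUMNS:
        raise SchemaError(
            f"expected columns {DATASET_COLUMNS}, found {list(df.columns)}"
        )
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    cgm = pd.to_numeric(df["cgm_mg_dl"], errors="coerce")
    bad = ts.isna() | cgm.isna()
    if bad.any():
        log.warning("%s: dropped %d unparseable rows", path, int(bad.sum()))
    df = df.loc[~bad].copy()
    df["timestamp"] = ts[~bad]
    df["cgm_mg_dl"] = cgm[~bad]
    for col in ("insulin_u", "cho_g"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    out: dict[str, pd.DataFrame] = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        g = (
            grp.groupby("timestamp", as_index=False)[["cgm_mg_dl", "insulin_u", "cho_g"]]
            .mean()
            .sort_values("timestamp")
            .reset_index(drop=True)
        )
        out[str(pid)] = g
    return out


def clean_and_resample(records: pd.DataFrame, patient_id: str, grid_min: int = 15) -> GlucoseSeries | None:
    """Bin one patient's records to a regular grid and segment at long gaps.

    Glucose readings outside the physical sensor range [20, 600] mg/dL are
    dropped as bad entries.  Readings are assigned to half-open bins
    ``[t, t + grid_min)`` labeled by the left edge; the bin glucose value
    is the mean of its contributions, carbohydrates and insulin are summed.
    Missing bins spanning at most 60 min are filled by linear
    interpolation; longer gaps start a new segment.  Returns ``None`` (with
    a logged warning) for patients with fewer than 16 usable grid points.
    """
    if len(records) < 2:
        log.warning("%s: fewer than 2 valid rows, excluded", patient_id)
        return None
    keep = records["cgm_mg_dl"].between(GLUCOSE_FLOOR, GLUCOSE_CEIL)
    dropped = int((~keep).sum())
    if dropped:
        log.warning("%s: dropped %d out-of-range cgm readings", patient_id, dropped)
    rec = records.loc[keep]
    if len(rec) < 2:
        log.warning("%s: no usable rows after range filter, excluded", patient_id)
        return None

    binned = rec["timestamp"].dt.floor(f"{grid_min}min")
    g = rec.assign(_bin=binned).groupby("_bin")
    cgm = g["cgm_mg_dl"].mean()
    cho = g["cho_g"].sum(min_count=1).fillna(0.0)
    ins = g["insulin_u"].sum(min_count=1).fillna(0.0)
    if len(cgm) < MIN_GRID_POINTS:
        log.warning("%s: only %d grid points (<%d), excluded", patient_id, len(cgm), MIN_GRID_POINTS)
        return None

    full_index = pd.date_range(cgm.index[0], cgm.index[-1], freq=f"{grid_min}min")
    cgm_full = cgm.reindex(full_index)
    cho_full = cho.reindex(full_index, fill_value=0.0)
    ins_full = ins.reindex(full_index, fill_value=0.0)

    # bridge short dropouts only: a run of missing bins is interpolated iff
    # the observed-to-observed gap it sits in is <= MAX_GAP_FILL_MIN
    max_fill_bins = MAX_GAP_FILL_MIN // grid_min
    observed = cgm_full.notna().to_numpy()
    filled = cgm_full.interpolate(method="time", limit_area="inside")
    missing_runs = _runs(~observed)
    keep_mask = np.ones(len(full_index), dtype=bool)
    seg_break = np.zeros(len(full_index), dtype=bool)
    for start, stop in missing_runs:
        run_len = stop - start
        # gap between surrounding observations is (run_len + 1) grid steps
        if (run_len + 1) * grid_min > MAX_GAP_FILL_MIN or run_len > max_fill_bins:
            keep_mask[start:stop] = False
            if stop < len(full_index):
                seg_break[stop] = True

    idx = full_index[keep_mask]
    cgm_arr = filled.to_numpy()[keep_mask]
    seg = np.cumsum(seg_break[keep_mask]).astype(np.int64)
    return GlucoseSeries(
        patient_id=patient_id,
        timestamps=idx,
        cgm=cgm_arr,
        segment_ids=seg,
        insulin=ins_full.to_numpy()[keep_mask],
        cho=cho_full.to_numpy()[keep_mask],
        grid_min=grid_min,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True in a boolean array."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def _slice_series(series: GlucoseSeries, sl: slice | np.ndarray) -> GlucoseSeries:
    return GlucoseSeries(
        patient_id=series.patient_id,
        timestamps=series.timestamps[sl],
        cgm=series.cgm[sl],
        segment_ids=series.segment_ids[sl],
        insulin=None if series.insulin is None else series.insulin[sl],
        cho=None if series.cho is None else series.cho[sl],
        grid_min=series.grid_min,
    )


def write_series_csv(series_by_patient: dict[str, GlucoseSeries], path) -> None:
    """Persist cleaned 15-min series (all patients) as one long CSV."""
    frames = []
    for pid, s in series_by_patient.items():
        f = s.to_frame().reset_index(names="timestamp")
        f.insert(0, "patient_id", pid)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_series_csv(path) -> dict[str, GlucoseSeries]:
    """Inverse of :func:`write_series_csv`."""
    df = pd.read_csv(path, parse_dates=["timestamp"], dtype={"patient_id": str})
    out = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("timestamp")
        out[str(pid)] = GlucoseSeries(
            patient_id=str(pid),
            timestamps=pd.DatetimeIndex(grp["timestamp"]),
            cgm=grp["cgm"].to_numpy(dtype=float),
            segment_ids=grp["segment_id"].to_numpy(dtype=np.int64),
            insulin=grp["insulin"].to_numpy(dtype=float) if "insulin" in grp else None,
            cho=grp["cho"].to_numpy(dtype=float) if "cho" in grp else None,
        )
    return out


def split_series(series: GlucoseSeries, spec: SplitSpec) -> tuple[GlucoseSeries, GlucoseSeries]:
    """Chronological cut: the first ``fraction`` of grid points train, the
    rest test.  Segment structure is preserved on both sides and no
    timestamp appears in both parts."""
    n = len(series)
    if n == 0:
        raise ValueError("cannot split an empty series")
    cut = int(round(n * spec.in_sample_fraction))
    if cut == 0 or cut == n:
        raise ValueError(
            f"in_sample_fraction={spec.in_sample_fraction} leaves one side empty (n={n})"
        )
    return _slice_series(series, slice(0, cut)), _slice_series(series, slice(cut, n))
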