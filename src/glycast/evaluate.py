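"""Confusion matrices, per-class scores and the comparative report.

Confusion matrices use the fixed class order hypo / norm / hyper, rows =
true class, columns = predicted class.  The row-normalized view rescales
each defined row to sum to 100% (rows with no true instances are reported
as missing, not zero, so a rare class absent from a test window is
distinguishable from total failure).  Per-patient matrices aggregate by
summing counts and then normalizing — count-weighted, so aggregate
accuracy equals accuracy over the pooled predictions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from glycast.features import CLASS_NAMES, CLASS_ORDER
from glycast.models.base import ClassPrediction

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "aggregate",
    "scores",
    "report",
]

_LABELS = [CLASS_NAMES[c] for c in CLASS_ORDER]


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 prediction counts with a row-normalized percentage view."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3) or np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be a nonnegative 3x3 integer matrix")

    @property
    def row_normalized(self) -> np.ndarray:
        """Rows as percentages of their true-class total; NaN for empty rows."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 100.0 * self.counts / totals
        out[totals[:, 0] == 0] = np.nan
        return out

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        data = self.row_normalized if normalized else self.counts
        return pd.DataFrame(data, index=_LABELS, columns=_LABELS)


def confusion_matrix(predictions: list[ClassPrediction]) -> ConfusionMatrix:
    """Count predictions on the fixed 3x3 class grid."""
    if not predictions:
        raise ValueError("no predictions to score")
    counts = np.zeros((3, 3), dtype=np.int64)
    idx = {c: i for i, c in enumerate(CLASS_ORDER)}
    for p in predictions:
        counts[idx[p.true_class], idx[p.predicted_class]] += 1
    return ConfusionMatrix(counts)


def aggregate(per_patient: list[ConfusionMatrix]) -> ConfusionMatrix:
    """Element-wise sum of counts; normalization happens on the sum."""
    if not per_patient:
        raise ValueError("nothing to aggregate")
    total = np.zeros((3, 3), dtype=np.int64)
    for cm in per_patient:
        total += cm.counts
    return ConfusionMatrix(total)


def scores(cm: ConfusionMatrix) -> dict:
    """Recall/precision/F1 per class plus overall accuracy.

    Undefined ratios (empty row or column, or both components of F1
    undefined/zero) are reported as NaN.
    """
    c = cm.counts.astype(float)
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    out: dict = {"accuracy": float(np.trace(c) / c.sum()) if c.sum() else math.nan}
    for i, cls in enumerate(CLASS_ORDER):
        name = CLASS_NAMES[cls]
        recall = c[i, i] / row[i] if row[i] else math.nan
        precision = c[i, i] / col[i] if col[i] else math.nan
        if math.isnan(recall) or math.isnan(precision) or (precision + recall) == 0:
            f1 = math.nan
        else:
            f1 = 2 * precision * recall / (precision + recall)
        out[f"recall_{name}"] = float(recall)
        out[f"precision_{name}"] = float(precision)
        out[f"f1_{name}"] = float(f1)
    return out


def report(results: dict[str, dict[str, ConfusionMatrix]], out_dir) -> dict:
    """Write the comparative score grid and per-model confusion matrices.

    ``results`` maps model name -> {horizon label -> aggregated matrix}.
    Emits ``scores.json`` (full precision), ``scores.csv`` (the
    model x horizon grid of per-class recall + accuracy), and one
    ``confusion_<model>_<horizon>.csv`` per cell with counts and the
    row-normalized view rounded to whole percent.  Missing model/horizon
    combinations stay in the grid as empty cells.  Returns the scores
    dict that was serialized.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_scores: dict = {}
    rows = []
    rounding_note = False
    for model_name, horizons in results.items():
        all_scores[model_name] = {}
        for horizon_label, cm in horizons.items():
            if cm is None:
                rows.append({"model": model_name, "horizon": horizon_label})
                continue
            sc = scores(cm)
            all_scores[model_name][horizon_label] = {
                **sc,
                "n_predictions": cm.total,
                "counts": cm.counts.tolist(),
                "row_normalized_pct": [
                    [None if math.isnan(v) else v for v in row] for row in cm.row_normalized
                ],
            }
            rows.append({
                "model": model_name,
                "horizon": horizon_label,
                "recall_hyper": sc["recall_hyper"],
                "recall_norm": sc["recall_norm"],
                "recall_hypo": sc["recall_hypo"],
                "accuracy": sc["accuracy"],
            })
            cm.to_frame().to_csv(out_dir / f"confusion_{model_name}_{horizon_label}.csv")
            rounded = cm.to_frame(normalized=True).round(0)
            rounded.to_csv(out_dir / f"confusion_{model_name}_{horizon_label}_pct.csv")
            row_sums = np.nansum(rounded.to_numpy(), axis=1)
            defined = ~np.isnan(cm.row_normalized).all(axis=1)
            if np.any(defined & (np.abs(row_sums - 100.0) > 1e-9)):
                rounding_note = True
    (out_dir / "scores.json").write_text(json.dumps(all_scores, indent=2))
    pd.DataFrame(rows).to_csv(out_dir / "scores.csv", index=False)
    if rounding_note:
        (out_dir / "ROUNDING_NOTE.txt").write_text(
            "Row-normalized confusion-matrix percentages are rounded to whole\n"
            "percent in the *_pct.csv views; rounded rows may not sum to exactly\n"
            "100%. The discrepancy is cosmetic; full precision is in scores.json.\n"
        )
    return all_scores
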