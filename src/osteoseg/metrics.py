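"""Confusion-matrix segmentation metrics.

All metrics derive from per-pixel confusion counts between a predicted and
a reference binary mask:

    IoU       = TP / (TP + FP + FN)
    DSC       = 2 TP / (2 TP + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)
    accuracy  = (TP + TN) / (TP + TN + FP + FN)

For pixelwise binary masks F1 and DSC coincide, and DSC = 2*IoU/(1+IoU).
Degenerate 0/0 ratios follow the usual empty-mask convention: if both masks
are empty the overlap metrics are 1 (perfect agreement), otherwise an
undefined ratio is reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SegMetrics", "confusion_counts", "compute_metrics",
           "metrics_from_masks", "metrics_table"]


@dataclass(frozen=True)
class SegMetrics:
    """Pixel confusion counts and the fractions derived from them."""

    tp: int
    tn: int
    fp: int
    fn: int
    iou: float
    dsc: float
    precision: float
    recall: float
    f1: float
    accuracy: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("tp", "tn", "fp", "fn", "iou", "dsc", "precision",
                 "recall", "f1", "accuracy")}


def confusion_counts(pred, truth) -> tuple[int, int, int, int]:
    """Exact pixel counts ``(tp, tn, fp, fn)`` for two binary masks."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    for name, m in (("pred", pred), ("truth", truth)):
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"{name} mask is not binary (values {vals})")
    p = pred.astype(bool)
    t = truth.astype(bool)
    tp = int(np.count_nonzero(p & t))
    tn = int(np.count_nonzero(~p & ~t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return tp, tn, fp, fn


def _ratio(num: float, den: float, empty_value: float) -> float:
    if den == 0:
        return empty_value
    return num / den


def compute_metrics(counts) -> SegMetrics:
    """Derive all metrics from a ``(tp, tn, fp, fn)`` quadruple."""
    tp, tn, fp, fn = (int(c) for c in counts)
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    both_empty = tp + fp + fn == 0
    sentinel = 1.0 if both_empty else 0.0
    iou = _ratio(tp, tp + fp + fn, sentinel)
    dsc = _ratio(2 * tp, 2 * tp + fp + fn, sentinel)
    precision = _ratio(tp, tp + fp, sentinel)
    recall = _ratio(tp, tp + fn, sentinel)
    f1 = _ratio(2 * precision * recall, precision + recall, sentinel)
    total = tp + tn + fp + fn
    accuracy = _ratio(tp + tn, total, 1.0)
    return SegMetrics(tp=tp, tn=tn, fp=fp, fn=fn, iou=iou, dsc=dsc,
                      precision=precision, recall=recall, f1=f1,
                      accuracy=accuracy)


def metrics_from_masks(pred, truth) -> SegMetrics:
    return compute_metrics(confusion_counts(pred, truth))


def metrics_table(rows: list[tuple[str, SegMetrics]]) -> pd.DataFrame:
    """Per-sample metric table with a mean row and a pooled-count row.

    The ``mean`` footer averages per-sample fractions; ``pooled`` recomputes
    every fraction from the summed confusion counts — the two conventions a
    reported image-set score may follow.
    """
    records = [{"sample": name, **m.as_dict()} for name, m in rows]
    df = pd.DataFrame.from_records(records)
    frac_cols = ["iou", "dsc", "precision", "recall", "f1", "accuracy"]
    mean_row = {"sample": "mean",
                **{c: float(df[c].mean()) for c in ["tp", "tn", "fp", "fn"]},
                **{c: float(df[c].mean()) for c in frac_cols}}
    pooled = compute_metrics(tuple(int(df[c].sum()) for c in ("tp", "tn", "fp", "fn")))
    pooled_row = {"sample": "pooled", **pooled.as_dict()}
    return pd.concat([df, pd.DataFrame.from_records([mean_row, pooled_row])],
                     ignore_index=True)
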