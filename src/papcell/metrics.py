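"""Segmentation and classification metrics.

Segmentation: accuracy, precision, recall, Dice, IoU from a pooled pixel
confusion (micro over all evaluated pixels; per-image averaging available).
Classification: accuracy, precision, recall, F1 with macro / weighted / micro
averaging and the full confusion matrix.  Zero-denominator ratios are reported
as 1 when the corresponding error count is also 0 and as 0 otherwise, so
degenerate inputs never produce NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PixelConfusion", "SegMetricReport", "ClfMetricReport",
           "pixel_confusion", "seg_metrics", "clf_metrics", "dice_score",
           "render_table"]


@dataclass(frozen=True)
class PixelConfusion:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class SegMetricReport:
    accuracy: float
    precision: float
    recall: float
    dice: float
    iou: float

    def as_percent_row(self) -> dict:
        return {k: round(100 * v, 2) for k, v in self.__dict__.items()}


@dataclass(frozen=True)
class ClfMetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    averaging: str

    def as_percent_row(self) -> dict:
        return {k: round(100 * getattr(self, k), 2)
                for k in ("accuracy", "precision", "recall", "f1")}


def _check_binary(arr):
    a = np.asarray(arr)
    if not np.isin(a, (0, 1)).all():
        raise ValueError("masks must be strictly binary {0,1}")
    return a.astype(bool)


def pixel_confusion(y_true, y_pred) -> PixelConfusion:
    """Pool TP/FP/TN/FN over all pixels of all images."""
    t = _check_binary(y_true)
    p = _check_binary(y_pred)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch {t.shape} vs {p.shape}")
    tp = int((t & p).sum())
    fp = int((~t & p).sum())
    fn = int((t & ~p).sum())
    tn = int((~t & ~p).sum())
    return PixelConfusion(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int, errors: int) -> float:
    if den == 0:
        return 1.0 if errors == 0 else 0.0
    return num / den


def seg_metrics(conf: PixelConfusion) -> SegMetricReport:
    tp, fp, tn, fn = conf.tp, conf.fp, conf.tn, conf.fn
    n = conf.total
    if n == 0:
        raise ValueError("empty confusion: no pixels evaluated")
    return SegMetricReport(
        accuracy=(tp + tn) / n,
        precision=_ratio(tp, tp + fp, fp),
        recall=_ratio(tp, tp + fn, fn),
        dice=_ratio(2 * tp, 2 * tp + fp + fn, fp + fn),
        iou=_ratio(tp, tp + fp + fn, fp + fn),
    )


def dice_score(y_true, y_pred) -> float:
    """Convenience: Dice coefficient of two binary mask batches."""
    return seg_metrics(pixel_confusion(y_true, y_pred)).dice


def clf_metrics(y_true, y_pred, n_classes: int,
                averaging: str = "weighted") -> ClfMetricReport:
    """Multi-class accuracy/precision/recall/F1 plus confusion matrix.

    Confusion rows are true classes, columns predicted.  ``averaging`` is one
    of macro / weighted / micro for the per-class aggregation.
    """
    if averaging not in ("macro", "weighted", "micro"):
        raise ValueError("averaging must be macro, weighted or micro")
    t = np.asarray(y_true, dtype=np.int64)
    p = np.asarray(y_pred, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label arrays must have the same length")
    if t.size == 0:
        raise ValueError("no samples to evaluate")
    for arr, name in ((t, "y_true"), (p, "y_pred")):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} labels out of range [0, {n_classes})")
    conf = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(conf, (t, p), 1)
    accuracy = conf.trace() / conf.sum()
    tp = np.diag(conf).astype(float)
    fp = conf.sum(axis=0) - tp
    fn = conf.sum(axis=1) - tp
    support = conf.sum(axis=1)
    if averaging == "micro":
        precision = _ratio(int(tp.sum()), int(tp.sum() + fp.sum()), int(fp.sum()))
        recall = _ratio(int(tp.sum()), int(tp.sum() + fn.sum()), int(fn.sum()))
        f1 = _ratio(int(2 * tp.sum()), int(2 * tp.sum() + fp.sum() + fn.sum()),
                    int(fp.sum() + fn.sum()))
    else:
        prec_c = np.array([_ratio(int(tp[i]), int(tp[i] + fp[i]), int(fp[i]))
                           for i in range(n_classes)])
        rec_c = np.array([_ratio(int(tp[i]), int(tp[i] + fn[i]), int(fn[i]))
                          for i in range(n_classes)])
        f1_c = np.array([_ratio(int(2 * tp[i]), int(2 * tp[i] + fp[i] + fn[i]),
                                int(fp[i] + fn[i])) for i in range(n_classes)])
        if averaging == "weighted":
            w = support / support.sum()
        else:
            w = np.full(n_classes, 1.0 / n_classes)
        precision = float(prec_c @ w)
        recall = float(rec_c @ w)
        f1 = float(f1_c @ w)
    return ClfMetricReport(accuracy=float(accuracy), precision=float(precision),
                           recall=float(recall), f1=float(f1),
                           confusion=conf, averaging=averaging)


def render_table(rows: list[dict]) -> pd.DataFrame:
    """Comparison table rendering (pipelines x metric columns, percentages)."""
    return pd.DataFrame(rows)
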