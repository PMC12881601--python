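"""Training losses with analytic gradients w.r.t. the model output."""

from __future__ import annotations

import numpy as np

_CLIP = 1e-7


def jaccard_distance(y_true, y_pred, smooth=100.0):
    """Jaccard distance 1 - IoU with additive smoothing over pooled sums.

    loss = 1 - (sum(t*p) + s) / (sum(t) + sum(p) - sum(t*p) + s)
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    inter = float((y_true * y_pred).sum())
    union = float(y_true.sum() + y_pred.sum() - inter)
    return 1.0 - (inter + smooth) / (union + smooth)


def jaccard_distance_grad(y_true, y_pred, smooth=100.0):
    """d loss / d y_pred (same shape as y_pred)."""
    t = np.asarray(y_true, dtype=np.float64)
    p = np.asarray(y_pred, dtype=np.float64)
    inter = (t * p).sum()
    union = t.sum() + p.sum() - inter
    num = inter + smooth
    den = union + smooth
    # d inter/dp = t ; d union/dp = 1 - t
    grad = -(t * den - num * (1.0 - t)) / den ** 2
    return grad.astype(np.float32)


def binary_crossentropy(y_true, y_pred):
    p = np.clip(y_pred, _CLIP, 1 - _CLIP)
    return float(-(y_true * np.log(p) + (1 - y_true) * np.log(1 - p)).mean())


def binary_crossentropy_grad(y_true, y_pred):
    p = np.clip(y_pred, _CLIP, 1 - _CLIP)
    return ((p - y_true) / (p * (1 - p)) / y_true.size).astype(np.float32)


def categorical_crossentropy(y_true, y_pred):
    p = np.clip(y_pred, _CLIP, 1.0)
    return float(-(y_true * np.log(p)).sum() / y_true.shape[0])


def categorical_crossentropy_grad(y_true, y_pred):
    p = np.clip(y_pred, _CLIP, 1.0)
    return (-(y_true / p) / y_true.shape[0]).astype(np.float32)
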