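"""Metric implementations against brute-force loop oracles and scikit-learn."""

import numpy as np
import pytest
from sklearn.metrics import (accuracy_score, f1_score, jaccard_score,
                             precision_score, recall_score)

from papcell.metrics import (PixelConfusion, clf_metrics, dice_score,
                             pixel_confusion, seg_metrics)


def _loop_confusion(t, p):
    tp = fp = tn = fn = 0
    for a, b in zip(np.asarray(t).ravel(), np.asarray(p).ravel()):
        if a == 1 and b == 1:
            tp += 1
        elif a == 0 and b == 1:
            fp += 1
        elif a == 1 and b == 0:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def test_pixel_confusion_matches_loop_oracle(rng):
    for _ in range(50):
        t = (rng.random((4, 8, 8)) > 0.5).astype(np.uint8)
        p = (rng.random((4, 8, 8)) > 0.5).astype(np.uint8)
        c = pixel_confusion(t, p)
        assert (c.tp, c.fp, c.tn, c.fn) == _loop_confusion(t, p)
        assert c.total == t.size


def test_pixel_confusion_rejects_nonbinary_and_mismatch():
    with pytest.raises(ValueError):
        pixel_confusion(np.array([0, 2]), np.array([0, 1]))
    with pytest.raises(ValueError):
        pixel_confusion(np.zeros((2, 2)), np.zeros((3, 2)))


def test_seg_metrics_agree_with_sklearn(rng):
    for seed in range(20):
        r = np.random.default_rng(seed)
        t = (r.random(256) > 0.4).astype(np.uint8)
        p = (r.random(256) > 0.6).astype(np.uint8)
        m = seg_metrics(pixel_confusion(t, p))
        assert m.accuracy == pytest.approx(accuracy_score(t, p))
        assert m.precision == pytest.approx(precision_score(t, p))
        assert m.recall == pytest.approx(recall_score(t, p))
        assert m.dice == pytest.approx(f1_score(t, p))
        assert m.iou == pytest.approx(jaccard_score(t, p))


def test_dice_iou_identity(rng):
    # dice = 2*iou/(1+iou) for every achievable confusion
    for _ in range(200):
        tp, fp, tn, fn = rng.integers(0, 50, 4)
        if tp + fp + tn + fn == 0:
            continue
        m = seg_metrics(PixelConfusion(int(tp), int(fp), int(tn), int(fn)))
        assert m.dice == pytest.approx(2 * m.iou / (1 + m.iou))


def test_zero_denominator_convention():
    # all-background truth and prediction: no errors -> ratios report 1
    m = seg_metrics(PixelConfusion(tp=0, fp=0, tn=10, fn=0))
    assert (m.precision, m.recall, m.dice, m.iou) == (1.0, 1.0, 1.0, 1.0)
    # all-background truth but positive prediction: precision has fp errors
    # -> 0; recall's denominator tp+fn is 0 with no fn errors -> vacuously 1
    m = seg_metrics(PixelConfusion(tp=0, fp=5, tn=5, fn=0))
    assert m.precision == 0.0 and m.recall == 1.0
    assert m.dice == 0.0 and m.iou == 0.0
    with pytest.raises(ValueError):
        seg_metrics(PixelConfusion(0, 0, 0, 0))


def test_dice_score_known_value():
    t = np.array([[1, 1, 0, 0]])
    p = np.array([[1, 0, 0, 0]])
    assert dice_score(t, p) == pytest.approx(2 / 3)


def test_clf_metrics_match_sklearn_all_averagings(rng):
    for seed in range(10):
        r = np.random.default_rng(seed)
        y = r.integers(0, 4, 200)
        p = np.where(r.random(200) < 0.7, y, r.integers(0, 4, 200))
        for avg in ("macro", "weighted", "micro"):
            m = clf_metrics(y, p, 4, averaging=avg)
            assert m.accuracy == pytest.approx(accuracy_score(y, p))
            assert m.precision == pytest.approx(
                precision_score(y, p, average=avg, zero_division=1))
            assert m.recall == pytest.approx(
                recall_score(y, p, average=avg, zero_division=1))
            assert m.f1 == pytest.approx(
                f1_score(y, p, average=avg, zero_division=1))


def test_clf_confusion_matrix_layout():
    y = np.array([0, 0, 1, 2])
    p = np.array([0, 1, 1, 0])
    m = clf_metrics(y, p, 3)
    expected = np.array([[1, 1, 0], [0, 1, 0], [1, 0, 0]])
    assert np.array_equal(m.confusion, expected)


def test_clf_metrics_validation():
    with pytest.raises(ValueError):
        clf_metrics([0, 1], [0], 2)
    with pytest.raises(ValueError):
        clf_metrics([0, 2], [0, 1], 2)
    with pytest.raises(ValueError):
        clf_metrics([], [], 2)
    with pytest.raises(ValueError):
        clf_metrics([0], [0], 2, averaging="harmonic")


def test_percent_rows_round_to_two_decimals():
    m = seg_metrics(PixelConfusion(tp=3, fp=1, tn=5, fn=1))
    row = m.as_percent_row()
    assert row["accuracy"] == 80.0
    assert row["dice"] == 75.0
    c = clf_metrics([0, 1, 1], [0, 1, 0], 2)
    assert set(c.as_percent_row()) == {"accuracy", "precision", "recall", "f1"}
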