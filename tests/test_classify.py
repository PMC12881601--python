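import itertools

import numpy as np
import pytest

from papcell.classify import (BACKBONE_NAMES, VOTING_MEMBER_NAMES,
                              BackboneSpec, ClfTrainConfig,
                              ConcatEnsembleConfig, VotingConfig,
                              backbone_checksum, build_backbone,
                              build_concat_ensemble, build_single_classifier,
                              majority_vote, predict, train_classifier)
from papcell.nn import count_module_parameters


def test_registry_contents():
    assert len(BACKBONE_NAMES) == 8
    assert len(VOTING_MEMBER_NAMES) == 7
    assert set(VOTING_MEMBER_NAMES) == set(BACKBONE_NAMES) - {"InceptionV3"}
    with pytest.raises(ValueError):
        BackboneSpec("AlexNet")


def test_backbones_differ_and_are_reproducible():
    sums = set()
    for name in BACKBONE_NAMES:
        b1 = build_backbone(BackboneSpec(name))
        b2 = build_backbone(BackboneSpec(name))
        assert backbone_checksum(b1) == backbone_checksum(b2)
        sums.add(round(backbone_checksum(b1), 6))
    assert len(sums) == 8  # every member sees a different feature space


def test_frozen_backbone_parameters_counted_non_trainable():
    frozen = build_backbone(BackboneSpec("VGG16", frozen=True))
    free = build_backbone(BackboneSpec("VGG16", frozen=False))
    tf, trf, ntf = count_module_parameters(frozen)
    t, tr, nt = count_module_parameters(free)
    assert tf == t
    assert trf == 0 and ntf == t
    assert tr == t and nt == 0


def test_majority_vote_matches_enumeration_oracle():
    # all 27 vote patterns of 3 models over 3 classes
    for votes in itertools.product(range(3), repeat=3):
        row = np.array([votes])
        got = majority_vote(row)[0]
        counts = [votes.count(c) for c in range(3)]
        best = max(counts)
        expected = min(c for c in range(3) if counts[c] == best)  # lowest index tie
        assert got == expected


def test_majority_vote_validation():
    with pytest.raises(ValueError):
        majority_vote(np.empty((0, 3), dtype=int))
    with pytest.raises(ValueError):
        majority_vote(np.array([1, 2, 3]))
    with pytest.raises(ValueError):
        majority_vote(np.array([[0, 1]]), tie_break="random")


def test_voting_config_validation():
    VotingConfig()  # default is valid
    with pytest.raises(ValueError):
        VotingConfig(members=tuple(BackboneSpec(n) for n in BACKBONE_NAMES))


def test_concat_ensemble_structure(rng):
    cfg = ConcatEnsembleConfig(n_classes=3, input_size=32)
    model = build_concat_ensemble(cfg, rng)
    assert len(model.backbones) == 8
    feats = model.extract_features(rng.random((2, 32, 32, 3)).astype(np.float32))
    assert feats.shape == (2, model.concat_dim)
    assert model.concat_dim == sum(model.feature_dims)
    p = model.forward(rng.random((2, 32, 32, 3)).astype(np.float32))
    assert p.shape == (2, 3)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)


def test_concat_ensemble_head_param_closed_form(rng):
    cfg = ConcatEnsembleConfig(n_classes=2, input_size=32)
    model = build_concat_ensemble(cfg, rng)
    d = model.concat_dim
    # Dense(d,256)+BN(256) + Dense(256,64) + Dense(64,2), biases included
    expected = (d * 256 + 256) + 2 * 256 + (256 * 64 + 64) + (64 * 2 + 2)
    head_params = sum(int(np.prod(s)) for l in model.head.layers()
                      for s in l.param_shapes().values())
    assert head_params == expected


def test_concat_ensemble_requires_eight_frozen_backbones():
    with pytest.raises(ValueError):
        ConcatEnsembleConfig(backbones=tuple(
            BackboneSpec(n) for n in BACKBONE_NAMES[:4]))
    with pytest.raises(ValueError):
        ConcatEnsembleConfig(backbones=tuple(
            BackboneSpec(n, frozen=False) for n in BACKBONE_NAMES))


def _blobs(n, rng, size=16):
    """Linearly separable two-class image set: dark vs bright."""
    y = rng.integers(0, 2, n)
    x = rng.random((n, size, size, 3)).astype(np.float32) * 0.3
    x[y == 1] += 0.6
    return np.clip(x, 0, 1), y


def test_single_classifier_learns_separable_data(rng):
    x, y = _blobs(80, rng)
    xv, yv = _blobs(24, rng)
    model = build_single_classifier(BackboneSpec("ResNet50V2", frozen=False),
                                    2, input_size=16, rng=rng)
    model, hist = train_classifier(
        model, x, y, xv, yv,
        ClfTrainConfig(max_epochs=20, learning_rate=5e-3, seed=0), 2)
    acc = (predict(model, xv).argmax(1) == yv).mean()
    assert acc >= 0.9
    assert hist[-1]["val_loss"] <= hist[0]["val_loss"]


def test_train_rejects_absent_class(rng):
    x, y = _blobs(20, rng)
    model = build_single_classifier(BackboneSpec("VGG16", frozen=False), 3,
                                    input_size=16, rng=rng)
    with pytest.raises(ValueError):
        train_classifier(model, x, np.zeros_like(y), x, y,
                         ClfTrainConfig(max_epochs=1), 3)


def test_training_is_seed_deterministic(rng):
    x, y = _blobs(40, rng)
    xv, yv = _blobs(12, rng)
    out = []
    for _ in range(2):
        m = build_single_classifier(BackboneSpec("VGG19", frozen=False), 2,
                                    input_size=16, rng=np.random.default_rng(7))
        m, h = train_classifier(m, x, y, xv, yv,
                                ClfTrainConfig(max_epochs=3, seed=4), 2)
        out.append((h, predict(m, xv)))
    assert out[0][0] == out[1][0]
    assert np.array_equal(out[0][1], out[1][1])


def test_frozen_backbones_unchanged_by_training(rng):
    cfg = ConcatEnsembleConfig(n_classes=2, input_size=16)
    model = build_concat_ensemble(cfg, rng)
    sums_before = [backbone_checksum(b) for b in model.backbones]
    x, y = _blobs(40, rng)
    xv, yv = _blobs(12, rng)
    model, _ = train_classifier(model, x, y, xv, yv,
                                ClfTrainConfig(max_epochs=2, seed=0), 2)
    assert [backbone_checksum(b) for b in model.backbones] == sums_before


def test_predict_rows_on_simplex(rng):
    model = build_single_classifier(BackboneSpec("Xception"), 4,
                                    input_size=16, rng=rng)
    p = predict(model, rng.random((5, 16, 16, 3)).astype(np.float32))
    assert p.shape == (5, 4)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)
    assert (p >= 0).all()
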