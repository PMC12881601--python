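import dataclasses
import json

import numpy as np
import pytest

from papcell.phantoms import PhantomSpec, generate_dataset
from papcell.unet import (IMPROVED_UNET, STANDARD_UNET, ParamCount,
                          SegModelConfig, TrainConfig, UNet, architecture_json,
                          build_unet, count_parameters, jaccard_distance_loss,
                          predict_mask, reconcile_architecture, train_segmenter)

# published parameter accounting for the two 224x224 variants
STANDARD_COUNTS = ParamCount(total=31_466_753, trainable=31_454_721,
                             non_trainable=12_032)
IMPROVED_COUNTS = ParamCount(total=31_454_721, trainable=31_454_721,
                             non_trainable=0)


def test_standard_unet_parameter_count():
    assert count_parameters(UNet(STANDARD_UNET)) == STANDARD_COUNTS


def test_improved_unet_parameter_count():
    assert count_parameters(UNet(IMPROVED_UNET)) == IMPROVED_COUNTS


def test_norm_swap_changes_only_non_trainable_count():
    batch = count_parameters(UNet(STANDARD_UNET))
    group = count_parameters(UNet(dataclasses.replace(STANDARD_UNET, norm="group")))
    assert group.trainable == batch.trainable
    assert group.non_trainable == 0
    assert batch.non_trainable == 12_032


def test_dilation_changes_no_counts():
    for d in (1, 2, 3):
        cfg = dataclasses.replace(IMPROVED_UNET, encoder_dilation=d)
        assert count_parameters(UNet(cfg)) == IMPROVED_COUNTS


def test_reconciliation_recovers_published_architecture():
    exact, candidates = reconcile_architecture(STANDARD_COUNTS)
    assert exact is not None
    assert exact.base_filters == 32
    assert exact.depth == 5
    assert exact.upsampling == "upsample"
    assert exact.conv_bias is True
    # the match is unique within the search grid
    exact_matches = [c for c, dt, dn in candidates if dt == 0 and dn == 0]
    assert len(exact_matches) == 1


def test_reconciliation_returns_none_without_match():
    target = ParamCount(total=12_345, trainable=12_345, non_trainable=0)
    exact, candidates = reconcile_architecture(target)
    assert exact is None
    assert len(candidates) > 0


def test_param_count_validation():
    with pytest.raises(ValueError):
        ParamCount(total=10, trainable=5, non_trainable=4)
    with pytest.raises(ValueError):
        ParamCount(total=-1, trainable=-1, non_trainable=0)


def test_config_validation():
    with pytest.raises(ValueError):
        SegModelConfig(norm="layer")
    with pytest.raises(ValueError):
        SegModelConfig(encoder_dilation=0)
    with pytest.raises(ValueError):
        SegModelConfig(upsampling="pixel_shuffle")


def test_filter_schedule_doubles_from_base():
    cfg = SegModelConfig(base_filters=8, depth=3)
    assert cfg.encoder_filters == (8, 16, 32)
    assert cfg.bottleneck_filters == 64


def _tiny_cfg(size=32):
    return SegModelConfig(input_size=size, depth=2, base_filters=4,
                          norm="group", groups=4, encoder_dilation=2,
                          dropout_rate=0.0)


def test_forward_shape_and_range(rng):
    model = build_unet(_tiny_cfg(), rng)
    x = rng.random((2, 32, 32, 3)).astype(np.float32)
    y = model.forward(x)
    assert y.shape == (2, 32, 32, 1)
    assert y.min() >= 0.0 and y.max() <= 1.0


def test_full_model_gradient_check(rng):
    """Directional-derivative check through the entire tiny U-Net.

    Perturbing every parameter along a random direction keeps the loss change
    well above float32 noise, unlike per-element finite differences.
    """
    model = build_unet(_tiny_cfg(), rng)
    x = rng.random((2, 32, 32, 3)).astype(np.float64)
    t = (rng.random((2, 32, 32, 1)) > 0.5).astype(np.float64)

    def loss():
        q = model.forward(x, training=True)
        return float(((q - t) ** 2).sum() / (2 * q.size))

    p = model.forward(x, training=True)
    model.backward((p - t) / p.size)
    rr = np.random.default_rng(1)
    direction = {}
    analytic = 0.0
    for li, layer in enumerate(model.layers()):
        for name in layer.param_shapes():
            v = rr.standard_normal(layer.params[name].shape)
            direction[(li, name)] = v
            analytic += float((layer.grads[name] * v).sum())
            # float64 params: eps must sit below the ReLU/MaxPool kink scale
            layer.params[name] = layer.params[name].astype(np.float64)
    eps = 1e-6
    evals = {}
    for sign in (+1, -1):
        for (li, name), v in direction.items():
            model.layers()[li].params[name] += sign * eps * v
        evals[sign] = loss()
        for (li, name), v in direction.items():
            model.layers()[li].params[name] -= sign * eps * v
    numeric = (evals[+1] - evals[-1]) / (2 * eps)
    assert analytic == pytest.approx(numeric, rel=1e-3)


def test_jaccard_loss_wrapper():
    t = np.array([1.0, 1.0, 0.0, 0.0])
    p = np.array([1.0, 0.0, 0.0, 0.0])
    assert jaccard_distance_loss(t, p, smooth=1.0) == pytest.approx(1 / 3)


def test_training_reduces_loss_and_is_deterministic():
    spec = PhantomSpec(image_size=32)
    samples, _ = generate_dataset(spec, {"normal": 16, "abnormal": 16}, seed=2)
    train, val = samples[:24], samples[24:]
    cfg = _tiny_cfg()
    tcfg = TrainConfig(max_epochs=4, batch_size=8, seed=0)
    m1, h1 = train_segmenter(build_unet(cfg), train, val, tcfg)
    m2, h2 = train_segmenter(build_unet(cfg), train, val, tcfg)
    assert h1[-1]["train_loss"] < h1[0]["train_loss"]
    assert h1 == h2  # bitwise-deterministic under a fixed seed
    p1 = predict_mask(m1, np.stack([s.image for s in val]))
    p2 = predict_mask(m2, np.stack([s.image for s in val]))
    assert np.array_equal(p1, p2)


def test_early_stopping_restores_best_weights():
    spec = PhantomSpec(image_size=32)
    samples, _ = generate_dataset(spec, {"normal": 10, "abnormal": 10}, seed=3)
    tcfg = TrainConfig(max_epochs=30, batch_size=8, seed=0,
                       early_stop_patience=2, stop_at_val_dice=0.99)
    model, hist = train_segmenter(build_unet(_tiny_cfg()), samples[:14],
                                  samples[14:], tcfg)
    assert len(hist) <= 30
    val_losses = [h["val_loss"] for h in hist]
    # restored weights reproduce the best recorded validation loss
    x_va = np.stack([s.image for s in samples[14:]])
    y_va = np.stack([s.mask for s in samples[14:]]).astype(np.float32)[..., None]
    p = predict_mask(model, x_va)
    from papcell.nn.losses import jaccard_distance
    assert jaccard_distance(y_va, p, 100.0) == pytest.approx(min(val_losses), abs=1e-6)


def test_predict_mask_rejects_wrong_size(rng):
    model = build_unet(_tiny_cfg(), rng)
    with pytest.raises(ValueError):
        predict_mask(model, rng.random((1, 48, 48, 3)).astype(np.float32))


def test_architecture_json_roundtrip(rng):
    model = build_unet(_tiny_cfg())
    d = json.loads(architecture_json(model))
    assert d["base_filters"] == 4
    assert d["param_count"]["total"] == count_parameters(model).total
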