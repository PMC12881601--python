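"""Finite-difference gradient checks and behavioural tests for the layer zoo."""

import numpy as np
import pytest

from papcell import nn
from papcell.nn.losses import (binary_crossentropy, binary_crossentropy_grad,
                               categorical_crossentropy,
                               categorical_crossentropy_grad, jaccard_distance,
                               jaccard_distance_grad)


def _fd_check_layer(layer, x, seed=0, eps=1e-3, tol=3e-2, check_params=True):
    """Compare analytic grads of sum(forward(x) * R) against central FD."""
    rng = np.random.default_rng(seed)
    if layer.param_shapes() and not layer.built:
        layer.build(rng)
    y = layer.forward(x, training=True)
    r = rng.standard_normal(y.shape)
    loss = lambda out: float((np.asarray(out, np.float64) * r).sum())
    dx = layer.backward(r)

    def fd(get, set_):
        base = get().copy()
        g = np.zeros_like(base, dtype=np.float64)
        it = np.nditer(base, flags=["multi_index"])
        while not it.finished:
            ix = it.multi_index
            for sgn in (+1, -1):
                pert = base.copy()
                pert[ix] += sgn * eps
                set_(pert)
                g[ix] += sgn * loss(layer.forward(x, training=True))
            it.iternext()
        set_(base)
        return g / (2 * eps)

    def rel(a, b):
        denom = max(np.abs(a).max(), np.abs(b).max(), 1e-4)
        return np.abs(a - b).max() / denom

    gx = fd(lambda: x, lambda v: x.__setitem__(Ellipsis, v))
    assert rel(np.asarray(dx, np.float64), gx) < tol, "input gradient mismatch"
    if check_params:
        for name in layer.param_shapes():
            layer.forward(x, training=True)
            layer.backward(r)
            analytic = layer.grads[name].astype(np.float64)
            def getp(n=name):
                return layer.params[n]
            def setp(v, n=name):
                layer.params[n][...] = v
            numeric = fd(getp, setp)
            assert rel(analytic, numeric) < tol, f"param {name} gradient mismatch"


@pytest.mark.parametrize("stride,dilation", [(1, 1), (2, 1), (1, 2)])
def test_conv2d_gradients(rng, stride, dilation):
    layer = nn.Conv2D(2, 3, 3, stride=stride, dilation=dilation)
    x = rng.standard_normal((2, 6, 6, 2)).astype(np.float32)
    _fd_check_layer(layer, x)


def test_conv_transpose_gradients(rng):
    layer = nn.ConvTranspose2D(2, 3, k=4, stride=2, pad=1)
    x = rng.standard_normal((2, 3, 3, 2)).astype(np.float32)
    _fd_check_layer(layer, x)


def test_conv_transpose_output_size(rng):
    layer = nn.ConvTranspose2D(2, 3, k=4, stride=2, pad=1)
    layer.build(rng)
    y = layer.forward(rng.standard_normal((1, 5, 5, 2)).astype(np.float32))
    assert y.shape == (1, 10, 10, 3)  # (H-1)s - 2p + k


def test_dense_gradients(rng):
    layer = nn.Dense(5, 4)
    x = rng.standard_normal((3, 5)).astype(np.float32)
    _fd_check_layer(layer, x)


def test_batchnorm_gradients_and_stats(rng):
    layer = nn.BatchNorm(3)
    # float64 input: normalization gradients are tiny, so fd needs precision
    x = rng.standard_normal((4, 3, 3, 3))
    _fd_check_layer(layer, x)
    layer.forward(x, training=True)
    mean_before = layer.non_trainable["moving_mean"].copy()
    layer.forward(x + 10, training=True)
    assert not np.allclose(layer.non_trainable["moving_mean"], mean_before)
    # eval mode uses running stats: output differs from train-mode output
    y_eval = layer.forward(x, training=False)
    assert np.isfinite(y_eval).all()


def test_groupnorm_gradients_and_batch_independence(rng):
    layer = nn.GroupNorm(4, groups=2)
    x = rng.standard_normal((2, 3, 3, 4))
    _fd_check_layer(layer, x)
    # per-sample normalization: result for sample 0 is batch-size invariant
    layer2 = nn.GroupNorm(4, groups=2)
    layer2.build(np.random.default_rng(0))
    layer2.params["gamma"][...] = layer.params["gamma"]
    layer2.params["beta"][...] = layer.params["beta"]
    full = layer.forward(x, training=True)
    solo = layer2.forward(x[:1], training=True)
    assert np.allclose(full[:1], solo, atol=1e-5)


def test_groupnorm_requires_divisible_groups():
    with pytest.raises(ValueError):
        nn.GroupNorm(6, groups=4).build(np.random.default_rng(0))


def test_maxpool_routes_gradient_to_argmax(rng):
    layer = nn.MaxPool2D(2)
    x = rng.standard_normal((1, 4, 4, 1)).astype(np.float32)
    y = layer.forward(x, training=True)
    assert y.shape == (1, 2, 2, 1)
    assert y[0, 0, 0, 0] == x[0, :2, :2, 0].max()
    dout = np.ones_like(y)
    dx = layer.backward(dout)
    assert dx.sum() == pytest.approx(4.0)        # one unit per window
    for i in range(2):
        for j in range(2):
            win = x[0, 2 * i:2 * i + 2, 2 * j:2 * j + 2, 0]
            gwin = dx[0, 2 * i:2 * i + 2, 2 * j:2 * j + 2, 0]
            assert gwin.flat[np.argmax(win)] == 1.0


def test_upsampling_is_exact_adjoint(rng):
    layer = nn.UpSampling2D(2)
    x = rng.standard_normal((1, 3, 3, 2)).astype(np.float32)
    y = layer.forward(x, training=True)
    assert y.shape == (1, 6, 6, 2)
    assert np.array_equal(y[0, 0, 0], y[0, 1, 1])
    _fd_check_layer(layer, x)


@pytest.mark.parametrize("cls", [nn.ReLU, nn.Sigmoid, nn.TanhRescaled])
def test_activation_gradients(rng, cls):
    x = rng.standard_normal((3, 5)).astype(np.float32)
    _fd_check_layer(cls(), x)


def test_leaky_relu_slope(rng):
    layer = nn.LeakyReLU(0.2)
    x = np.array([[-2.0, 3.0]], dtype=np.float32)
    y = layer.forward(x, training=True)
    assert np.allclose(y, [[-0.4, 3.0]])
    _fd_check_layer(layer, rng.standard_normal((3, 5)).astype(np.float32))


def test_softmax_rows_and_gradient(rng):
    layer = nn.Softmax()
    x = rng.standard_normal((4, 6)).astype(np.float32)
    y = layer.forward(x, training=True)
    assert np.allclose(y.sum(axis=1), 1.0, atol=1e-6)
    _fd_check_layer(layer, x)


def test_dropout_train_vs_eval(rng):
    for cls in (nn.Dropout, nn.SpatialDropout2D):
        layer = cls(0.5)
        layer.rng = np.random.default_rng(0)
        shape = (8, 4, 4, 6) if cls is nn.SpatialDropout2D else (8, 24)
        x = np.ones(shape, dtype=np.float32)
        y_eval = layer.forward(x, training=False)
        assert np.array_equal(y_eval, x)
        # eval backward with no stored mask is the identity
        assert np.array_equal(layer.backward(x), x)
        y_train = layer.forward(x, training=True)
        kept = y_train != 0
        assert 0 < kept.mean() < 1
        assert np.allclose(y_train[kept], 1 / 0.5, atol=1e-6)  # inverted scaling
        if cls is nn.SpatialDropout2D:
            # whole channels dropped per sample
            per_channel = y_train.reshape(8, -1, 6).std(axis=1)
            assert np.allclose(per_channel, 0, atol=1e-6)


def test_tanh_rescaled_range(rng):
    y = nn.TanhRescaled().forward(rng.standard_normal((5, 5)).astype(np.float32) * 10)
    assert y.min() >= 0.0 and y.max() <= 1.0


def test_adam_descends_quadratic():
    layer = nn.Dense(3, 1, bias=False)
    layer.build(np.random.default_rng(0))
    model = nn.Sequential([layer])
    opt = nn.Adam(model, lr=0.05)
    x = np.eye(3, dtype=np.float32)
    target = np.array([[1.0], [2.0], [3.0]], dtype=np.float32)
    first = None
    for _ in range(200):
        y = model.forward(x, training=True)
        diff = y - target
        if first is None:
            first = float((diff ** 2).sum())
        model.backward(2 * diff)
        opt.step()
        opt.zero_grad()
    last = float(((model.forward(x) - target) ** 2).sum())
    assert last < 1e-3 < first


def test_adam_skips_frozen_layers():
    layer = nn.Dense(2, 2)
    layer.build(np.random.default_rng(0))
    layer.frozen = True
    model = nn.Sequential([layer])
    opt = nn.Adam(model, lr=0.5)
    w0 = layer.params["W"].copy()
    x = np.ones((1, 2), dtype=np.float32)
    model.forward(x, training=True)
    model.backward(np.ones((1, 2), dtype=np.float32))
    opt.step()
    assert np.array_equal(layer.params["W"], w0)


# ---- loss functions ---------------------------------------------------------

def _fd_loss(fn, y_true, y_pred, eps=1e-4):
    g = np.zeros_like(y_pred, dtype=np.float64)
    it = np.nditer(y_pred, flags=["multi_index"])
    while not it.finished:
        ix = it.multi_index
        for sgn in (+1, -1):
            pert = y_pred.copy()
            pert[ix] += sgn * eps
            g[ix] += sgn * fn(y_true, pert)
        it.iternext()
    return g / (2 * eps)


def test_jaccard_distance_value():
    t = np.array([1.0, 1.0, 0.0, 0.0])
    p = np.array([1.0, 0.0, 0.0, 0.0])
    # intersection 1, union 2 -> 1 - (1+s)/(2+s); s=1 -> 1/3
    assert jaccard_distance(t, p, smooth=1.0) == pytest.approx(1 / 3)
    assert jaccard_distance(t, t, smooth=100.0) == pytest.approx(0.0)


def test_jaccard_distance_gradient(rng):
    t = (rng.random((2, 4, 4, 1)) > 0.5).astype(np.float64)
    p = rng.uniform(0.1, 0.9, (2, 4, 4, 1))
    g = jaccard_distance_grad(t, p, smooth=10.0)
    assert np.allclose(g, _fd_loss(lambda a, b: jaccard_distance(a, b, 10.0), t, p),
                       atol=1e-6)


def test_crossentropy_gradients(rng):
    t = (rng.random(6) > 0.5).astype(np.float64)
    p = rng.uniform(0.05, 0.95, 6)
    g = binary_crossentropy_grad(t, p)
    assert np.allclose(g, _fd_loss(binary_crossentropy, t, p), atol=1e-5)
    tc = np.eye(3)[rng.integers(0, 3, 4)]
    pc = rng.uniform(0.05, 0.95, (4, 3))
    pc /= pc.sum(1, keepdims=True)
    g = categorical_crossentropy_grad(tc, pc)
    assert np.allclose(g, _fd_loss(categorical_crossentropy, tc, pc), atol=1e-5)
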