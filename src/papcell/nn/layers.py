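"""Trainable layers over :mod:`papcell.nn.functional`.

A layer exposes ``param_shapes()`` (so parameter accounting never requires
allocating weights), ``build(rng)``, ``forward(x, training)`` and
``backward(dout)``.  Parameters and their gradients live in the ``params`` and
``grads`` dicts; ``non_trainable`` holds running statistics (batch norm).
"""

from __future__ import annotations

import numpy as np

from . import functional as F

_EPS = 1e-3  # normalization epsilon


class Layer:
    trainable = True

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.non_trainable: dict[str, np.ndarray] = {}
        self.built = False

    def param_shapes(self) -> dict[str, tuple]:
        return {}

    def non_trainable_shapes(self) -> dict[str, tuple]:
        return {}

    def build(self, rng: np.random.Generator):
        self.built = True

    def ensure_built(self, rng=None):
        if not self.built:
            self.build(rng if rng is not None else np.random.default_rng(0))

    def forward(self, x, training=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grad(self):
        self.grads = {}


def _he_normal(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2D(Layer):
    """3x3/kxk convolution, 'same' or 'valid' padding, optional dilation/stride."""

    def __init__(self, cin, cout, k=3, stride=1, dilation=1, padding="same", bias=True):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.dilation = stride, dilation
        self.use_bias = bias
        if padding == "same":
            self.pad = F.same_pad(k, dilation)
        elif padding == "valid":
            self.pad = 0
        else:
            self.pad = int(padding)

    def param_shapes(self):
        shapes = {"W": (self.k, self.k, self.cin, self.cout)}
        if self.use_bias:
            shapes["b"] = (self.cout,)
        return shapes

    def build(self, rng):
        fan_in = self.k * self.k * self.cin
        self.params["W"] = _he_normal(rng, (self.k, self.k, self.cin, self.cout), fan_in)
        if self.use_bias:
            self.params["b"] = np.zeros(self.cout, dtype=np.float32)
        self.built = True

    def forward(self, x, training=False):
        y, cols = F.conv2d(x, self.params["W"], self.params.get("b"),
                           self.stride, self.dilation, self.pad)
        if training:
            self._cols, self._x_shape = cols, x.shape
        return y

    def backward(self, dout):
        W = self.params["W"]
        self.grads["W"] = F.conv2d_grad_w(self._cols, dout).reshape(W.shape)
        if self.use_bias:
            self.grads["b"] = dout.sum(axis=(0, 1, 2))
        dx = F.conv2d_grad_x(dout, W, self._x_shape, self.stride, self.dilation, self.pad)
        self._cols = None
        return dx


class ConvTranspose2D(Layer):
    """Stride-s transposed convolution (learned up-sampling)."""

    def __init__(self, cin, cout, k=4, stride=2, pad=1, bias=True):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.pad = stride, pad
        self.use_bias = bias

    def param_shapes(self):
        shapes = {"W": (self.k, self.k, self.cout, self.cin)}
        if self.use_bias:
            shapes["b"] = (self.cout,)
        return shapes

    def build(self, rng):
        fan_in = self.k * self.k * self.cin
        self.params["W"] = _he_normal(rng, (self.k, self.k, self.cout, self.cin), fan_in)
        if self.use_bias:
            self.params["b"] = np.zeros(self.cout, dtype=np.float32)
        self.built = True

    def forward(self, x, training=False):
        if training:
            self._x = x
        return F.conv_transpose2d(x, self.params["W"], self.params.get("b"),
                                  self.stride, self.pad)

    def backward(self, dout):
        W = self.params["W"]
        # adjoint pair: dx is a plain strided conv of dout with W
        dx, cols = F.conv2d(dout, W, None, self.stride, 1, self.pad)
        self.grads["W"] = F.conv2d_grad_w(cols, self._x).reshape(W.shape)
        if self.use_bias:
            self.grads["b"] = dout.sum(axis=(0, 1, 2))
        self._x = None
        return dx


class Dense(Layer):
    def __init__(self, din, dout, bias=True):
        super().__init__()
        self.din, self.dout = din, dout
        self.use_bias = bias

    def param_shapes(self):
        shapes = {"W": (self.din, self.dout)}
        if self.use_bias:
            shapes["b"] = (self.dout,)
        return shapes

    def build(self, rng):
        self.params["W"] = _he_normal(rng, (self.din, self.dout), self.din)
        if self.use_bias:
            self.params["b"] = np.zeros(self.dout, dtype=np.float32)
        self.built = True

    def forward(self, x, training=False):
        if training:
            self._x = x
        y = x @ self.params["W"]
        if self.use_bias:
            y = y + self.params["b"]
        return y

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        if self.use_bias:
            self.grads["b"] = dout.sum(axis=0)
        dx = dout @ self.params["W"].T
        self._x = None
        return dx


class BatchNorm(Layer):
    """Channel-wise batch normalization with running statistics (NHWC or NC)."""

    def __init__(self, c, momentum=0.99, eps=_EPS):
        super().__init__()
        self.c, self.momentum, self.eps = c, momentum, eps

    def param_shapes(self):
        return {"gamma": (self.c,), "beta": (self.c,)}

    def non_trainable_shapes(self):
        return {"moving_mean": (self.c,), "moving_var": (self.c,)}

    def build(self, rng):
        self.params["gamma"] = np.ones(self.c, dtype=np.float32)
        self.params["beta"] = np.zeros(self.c, dtype=np.float32)
        self.non_trainable["moving_mean"] = np.zeros(self.c, dtype=np.float32)
        self.non_trainable["moving_var"] = np.ones(self.c, dtype=np.float32)
        self.built = True

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.non_trainable["moving_mean"] = (m * self.non_trainable["moving_mean"]
                                                 + (1 - m) * mean).astype(np.float32)
            self.non_trainable["moving_var"] = (m * self.non_trainable["moving_var"]
                                                + (1 - m) * var).astype(np.float32)
        else:
            mean = self.non_trainable["moving_mean"]
            var = self.non_trainable["moving_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._xhat, self._inv, self._axes = xhat, inv, axes
            self._m = x.size // x.shape[-1]
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, inv, axes, m = self._xhat, self._inv, self._axes, self._m
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"]
        dx = inv / m * (m * dxhat - dxhat.sum(axis=axes)
                        - xhat * (dxhat * xhat).sum(axis=axes))
        self._xhat = None
        return dx.astype(np.float32)


class GroupNorm(Layer):
    """Group normalization: per-sample statistics over channel groups."""

    def __init__(self, c, groups=32, eps=_EPS):
        super().__init__()
        groups = min(groups, c)
        if c % groups:
            raise ValueError(f"groups={groups} does not divide channels={c}")
        self.c, self.groups, self.eps = c, groups, eps

    def param_shapes(self):
        return {"gamma": (self.c,), "beta": (self.c,)}

    def build(self, rng):
        self.params["gamma"] = np.ones(self.c, dtype=np.float32)
        self.params["beta"] = np.zeros(self.c, dtype=np.float32)
        self.built = True

    def _group_view(self, x):
        n = x.shape[0]
        return x.reshape(n, -1, self.groups, self.c // self.groups)

    def forward(self, x, training=False):
        g = self._group_view(x)  # (N, S, G, C/G) with S = H*W (or 1)
        mean = g.mean(axis=(1, 3), keepdims=True)
        var = g.var(axis=(1, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        ghat = (g - mean) * inv
        xhat = ghat.reshape(x.shape)
        if training:
            self._xhat, self._inv = xhat, inv
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat = self._xhat
        axes = tuple(range(dout.ndim - 1))
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = (dout * self.params["gamma"])
        g = self._group_view(dxhat)
        ghat = self._group_view(xhat)
        m = g.shape[1] * g.shape[3]
        dg = self._inv / m * (m * g - g.sum(axis=(1, 3), keepdims=True)
                              - ghat * (g * ghat).sum(axis=(1, 3), keepdims=True))
        self._xhat = None
        return dg.reshape(dout.shape).astype(np.float32)


class MaxPool2D(Layer):
    trainable = False

    def __init__(self, size=2):
        super().__init__()
        self.size = size
        self.built = True

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        s = self.size
        xr = x.reshape(n, h // s, s, w // s, s, c).transpose(0, 1, 3, 2, 4, 5)
        xr = xr.reshape(n, h // s, w // s, s * s, c)
        arg = xr.argmax(axis=3)
        y = np.take_along_axis(xr, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if training:
            self._arg, self._x_shape = arg, x.shape
        return y

    def backward(self, dout):
        n, h, w, c = self._x_shape
        s = self.size
        dxr = np.zeros((n, h // s, w // s, s * s, c), dtype=dout.dtype)
        np.put_along_axis(dxr, self._arg[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = dxr.reshape(n, h // s, w // s, s, s, c).transpose(0, 1, 3, 2, 4, 5)
        return dx.reshape(n, h, w, c)


class UpSampling2D(Layer):
    """Parameter-free nearest-neighbour up-sampling."""

    trainable = False

    def __init__(self, size=2):
        super().__init__()
        self.size = size
        self.built = True

    def forward(self, x, training=False):
        return x.repeat(self.size, axis=1).repeat(self.size, axis=2)

    def backward(self, dout):
        n, h, w, c = dout.shape
        s = self.size
        return dout.reshape(n, h // s, s, w // s, s, c).sum(axis=(2, 4))


class SpatialDropout2D(Layer):
    """Drops entire feature maps; inverted scaling at train time."""

    trainable = False

    def __init__(self, rate=0.5):
        super().__init__()
        self.rate = rate
        self.rng = np.random.default_rng(0)
        self.built = True

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random((x.shape[0], 1, 1, x.shape[-1])) < keep) / keep
        self._mask = mask.astype(np.float32)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dropout(Layer):
    trainable = False

    def __init__(self, rate=0.5):
        super().__init__()
        self.rate = rate
        self.rng = np.random.default_rng(0)
        self.built = True

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(np.float32)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class ReLU(Layer):
    trainable = False

    def __init__(self):
        super().__init__()
        self.built = True

    def forward(self, x, training=False):
        if training:
            self._pos = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._pos


class LeakyReLU(Layer):
    trainable = False

    def __init__(self, alpha=0.2):
        super().__init__()
        self.alpha = alpha
        self.built = True

    def forward(self, x, training=False):
        if training:
            self._pos = x > 0
        return np.where(x > 0, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._pos, dout, self.alpha * dout)


class Sigmoid(Layer):
    trainable = False

    def __init__(self):
        super().__init__()
        self.built = True

    def forward(self, x, training=False):
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        if training:
            self._y = y
        return y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class TanhRescaled(Layer):
    """tanh output mapped from [-1, 1] to [0, 1]."""

    trainable = False

    def __init__(self):
        super().__init__()
        self.built = True

    def forward(self, x, training=False):
        t = np.tanh(x)
        if training:
            self._t = t
        return 0.5 * (t + 1.0)

    def backward(self, dout):
        return dout * 0.5 * (1.0 - self._t ** 2)


class Softmax(Layer):
    trainable = False

    def __init__(self):
        super().__init__()
        self.built = True

    def forward(self, x, training=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        if training:
            self._p = p
        return p

    def backward(self, dout):
        p = self._p
        return p * (dout - (dout * p).sum(axis=-1, keepdims=True))


class Flatten(Layer):
    trainable = False

    def __init__(self):
        super().__init__()
        self.built = True

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Reshape(Layer):
    trainable = False

    def __init__(self, shape):
        super().__init__()
        self.shape = shape
        self.built = True

    def forward(self, x, training=False):
        self._in = x.shape
        return x.reshape((x.shape[0],) + tuple(self.shape))

    def backward(self, dout):
        return dout.reshape(self._in)


class GlobalAvgPool2D(Layer):
    trainable = False

    def __init__(self):
        super().__init__()
        self.built = True

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), self._shape).astype(dout.dtype)
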