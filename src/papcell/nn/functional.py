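"""Low-level convolution arithmetic in NHWC layout.

All tensors are ``float32`` numpy arrays shaped ``(N, H, W, C)``; kernels are
``(kh, kw, Cin, Cout)`` as in Keras.  Convolutions are implemented as im2col +
one GEMM; the input gradient is a scatter-add through a cached index map, and
the transposed convolution reuses the same machinery as the adjoint of the
strided convolution.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# index maps keyed by (padded_shape, k, stride, dilation) -> flat scatter indices
_SCATTER_CACHE: dict = {}


def conv_out_size(size: int, k: int, stride: int, dilation: int, pad: int) -> int:
    eff = dilation * (k - 1) + 1
    return (size + 2 * pad - eff) // stride + 1


def same_pad(k: int, dilation: int) -> int:
    """Padding that preserves spatial size at stride 1 (odd effective kernels)."""
    return dilation * (k - 1) // 2


def im2col(x: np.ndarray, k: int, stride: int, dilation: int, pad: int) -> np.ndarray:
    """Return columns shaped ``(N, Ho, Wo, kh, kw, C)``."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    eff = dilation * (k - 1) + 1
    win = sliding_window_view(x, (eff, eff), axis=(1, 2))
    # win: (N, Ho', Wo', C, eff, eff); subsample stride and dilation taps
    win = win[:, ::stride, ::stride, :, ::dilation, ::dilation]
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))


def conv2d(x, W, b, stride=1, dilation=1, pad=0, cols_out=None):
    """Forward convolution; returns (y, cols) with cols reusable in backward."""
    k = W.shape[0]
    cols = im2col(x, k, stride, dilation, pad)
    n, ho, wo = cols.shape[:3]
    y = cols.reshape(n * ho * wo, -1) @ W.reshape(-1, W.shape[3])
    if b is not None:
        y += b
    return y.reshape(n, ho, wo, W.shape[3]), cols


def conv2d_grad_w(cols, dout):
    n, ho, wo, cout = dout.shape
    dW2 = cols.reshape(n * ho * wo, -1).T @ dout.reshape(n * ho * wo, cout)
    return dW2


def _scatter_indices(hp, wp, c, ho, wo, k, stride, dilation):
    key = (hp, wp, c, ho, wo, k, stride, dilation)
    idx = _SCATTER_CACHE.get(key)
    if idx is None:
        oh = np.arange(ho)[:, None, None, None]
        ow = np.arange(wo)[None, :, None, None]
        kh = np.arange(k)[None, None, :, None]
        kw = np.arange(k)[None, None, None, :]
        hi = oh * stride + kh * dilation
        wi = ow * stride + kw * dilation
        # (ho, wo, k, k) -> flat padded index per channel block
        idx = ((hi * wp + wi)[..., None] * c + np.arange(c)).ravel()
        _SCATTER_CACHE[key] = idx
    return idx


def conv2d_grad_x(dout, W, x_shape, stride=1, dilation=1, pad=0):
    """Scatter-add the column gradient back to the (unpadded) input."""
    n, h, w, cin = x_shape
    k = W.shape[0]
    ho, wo = dout.shape[1], dout.shape[2]
    hp, wp = h + 2 * pad, w + 2 * pad
    dcols = dout.reshape(n * ho * wo, -1) @ W.reshape(-1, W.shape[3]).T
    dcols = dcols.reshape(n, -1)  # (N, ho*wo*k*k*cin)
    idx = _scatter_indices(hp, wp, cin, ho, wo, k, stride, dilation)
    size = hp * wp * cin
    dxp = np.empty((n, size), dtype=dout.dtype)
    for i in range(n):
        dxp[i] = np.bincount(idx, weights=dcols[i], minlength=size)
    dxp = dxp.reshape(n, hp, wp, cin)
    if pad:
        dxp = dxp[:, pad:-pad, pad:-pad, :]
    return np.ascontiguousarray(dxp)


def conv_transpose2d(x, W, b, stride=2, pad=0, out_size=None):
    """Transposed convolution: the adjoint of ``conv2d`` with the same W.

    ``W`` is shaped ``(k, k, Cout, Cin)`` so that the paired forward
    convolution maps Cout -> Cin.  Output spatial size is
    ``(Hi - 1) * stride - 2 * pad + k`` unless ``out_size`` overrides it.
    """
    n, hi, wi, cin = x.shape
    k = W.shape[0]
    if out_size is None:
        out_size = (hi - 1) * stride - 2 * pad + k
    y = conv2d_grad_x(x, W, (n, out_size, out_size, W.shape[2]),
                      stride=stride, dilation=1, pad=pad)
    if b is not None:
        y = y + b
    return y
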