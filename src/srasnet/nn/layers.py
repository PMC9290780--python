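"""Minimal convolutional-network layers with explicit backpropagation.

All layers are written in a functional style: ``forward`` returns
``(output, cache)`` and ``backward(cache, grad_out)`` returns the gradient
with respect to the input while *accumulating* parameter gradients in
place.  Returning caches (instead of storing them on the layer) lets the
same layer object be applied several times inside one computation graph,
which is exactly what a recurrent feedback network with shared weights
needs for backpropagation through time.

Tensors are NCHW ``float32``; convolutions are stride-1 with symmetric
zero padding chosen so spatial dims are preserved.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Conv2d",
    "Deconv2d",
    "Dense",
    "ReLU",
    "MaxPool2",
    "GlobalAvgPool",
]


class Parameter:
    """A learnable array plus its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*kh*kw, H*W) column matrix for stride-1 conv."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    # win: (N, C, Ho, Wo, kh, kw) -> (N, C, kh, kw, Ho, Wo)
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, ho * wo)
    return np.ascontiguousarray(cols)


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add of columns back to image)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho, wo = hp - kh + 1, wp - kw + 1
    xp = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + ho, j:j + wo] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


class Conv2d:
    """Stride-1 2-D convolution with 'same' zero padding.

    Kaiming-uniform initialisation by default; ``zero_init`` produces an
    exactly-zero kernel and bias (used by the residual head so that an
    untrained network reduces to plain interpolation).
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 zero_init: bool = False):
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = (k - 1) // 2
        fan_in = cin * k * k
        if zero_init:
            w = np.zeros((cout, cin, k, k), dtype=np.float32)
        else:
            bound = np.sqrt(6.0 / fan_in)
            w = rng.uniform(-bound, bound, (cout, cin, k, k)).astype(np.float32)
        self.W = Parameter(w)
        self.b = Parameter(np.zeros(cout, dtype=np.float32))

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray):
        n, c, h, w = x.shape
        cols = _im2col(x, self.k, self.k, self.pad)
        wmat = self.W.data.reshape(self.cout, -1)
        out = np.einsum("oc,ncp->nop", wmat, cols, optimize=True)
        out += self.b.data[None, :, None]
        out = out.reshape(n, self.cout, h, w)
        return out, (cols, x.shape)

    def backward(self, cache, gout: np.ndarray):
        cols, x_shape = cache
        n = x_shape[0]
        g = gout.reshape(n, self.cout, -1)
        self.W.grad += np.einsum("nop,ncp->oc", g, cols,
                                 optimize=True).reshape(self.W.data.shape)
        self.b.grad += g.sum(axis=(0, 2))
        wmat = self.W.data.reshape(self.cout, -1)
        gcols = np.einsum("oc,nop->ncp", wmat, g, optimize=True)
        return _col2im(gcols, x_shape, self.k, self.k, self.pad)


class Deconv2d:
    """Transposed convolution: zero-stuff by ``scale`` then convolve.

    Inserting ``scale - 1`` zeros between samples and applying a learned
    kernel is the textbook decomposition of a stride-``scale`` transposed
    convolution; output dims are exactly ``scale`` times the input dims.
    The kernel is wide enough (5 for scale 4, else 3) that every output
    pixel receives at least one input sample.
    """

    def __init__(self, cin: int, cout: int, scale: int, rng: np.random.Generator):
        if scale < 2:
            raise ValueError("upsampling scale must be >= 2")
        self.scale = scale
        k = 5 if scale >= 4 else 3
        self.conv = Conv2d(cin, cout, k, rng)

    def parameters(self):
        return self.conv.parameters()

    def forward(self, x: np.ndarray):
        n, c, h, w = x.shape
        s = self.scale
        up = np.zeros((n, c, h * s, w * s), dtype=x.dtype)
        up[:, :, ::s, ::s] = x
        out, conv_cache = self.conv.forward(up)
        return out, (conv_cache,)

    def backward(self, cache, gout: np.ndarray):
        (conv_cache,) = cache
        gup = self.conv.backward(conv_cache, gout)
        s = self.scale
        return np.ascontiguousarray(gup[:, :, ::s, ::s])


class Dense:
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / din)
        self.W = Parameter(rng.uniform(-bound, bound, (din, dout)).astype(np.float32))
        self.b = Parameter(np.zeros(dout, dtype=np.float32))

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray):
        return x @ self.W.data + self.b.data, (x,)

    def backward(self, cache, gout: np.ndarray):
        (x,) = cache
        self.W.grad += x.T @ gout
        self.b.grad += gout.sum(axis=0)
        return gout @ self.W.data.T


class ReLU:
    def parameters(self):
        return []

    def forward(self, x: np.ndarray):
        out = np.maximum(x, 0.0)
        return out, (x > 0,)

    def backward(self, cache, gout: np.ndarray):
        (mask,) = cache
        return gout * mask


class MaxPool2:
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def parameters(self):
        return []

    def forward(self, x: np.ndarray):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
        out = xt.max(axis=(3, 5))
        mask = xt == out[:, :, :, None, :, None]
        return out, (mask, x.shape)

    def backward(self, cache, gout: np.ndarray):
        mask, x_shape = cache
        n, c, h, w = x_shape
        h2, w2 = h // 2, w // 2
        g = mask * gout[:, :, :, None, :, None]
        gx = np.zeros(x_shape, dtype=gout.dtype)
        gx[:, :, : h2 * 2, : w2 * 2] = g.reshape(n, c, h2 * 2, w2 * 2)
        return gx


class GlobalAvgPool:
    def parameters(self):
        return []

    def forward(self, x: np.ndarray):
        return x.mean(axis=(2, 3)), (x.shape,)

    def backward(self, cache, gout: np.ndarray):
        (x_shape,) = cache
        n, c, h, w = x_shape
        return np.broadcast_to(
            gout[:, :, None, None] / (h * w), x_shape
        ).astype(gout.dtype)
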