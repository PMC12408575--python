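"""Layers with hand-derived backward passes.

Conventions: sequence tensors are (batch, time, channels); image tensors are
(batch, channels, height, width).  Default dtype is float32 (``dtype`` is a
constructor argument so gradient-check tests can run in float64).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from dopplerauth.nn.core import Module, Parameter

__all__ = [
    "Dense", "LayerNorm", "ReLU", "Sigmoid", "SiLU", "GLU",
    "MultiHeadSelfAttention", "DepthwiseConv1d",
    "Conv2d", "ConvTranspose2d", "MaxPool2d", "Flatten",
]


def glorot(rng: np.random.Generator, shape, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Dense(Module):
    """Affine map on the last axis: y = x @ W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32, weight_scale: float | None = None):
        if weight_scale is None:
            w = glorot(rng, (n_in, n_out), n_in, n_out, dtype)
        else:
            w = (weight_scale * rng.standard_normal((n_in, n_out))).astype(dtype)
        self.W = Parameter(w)
        self.b = Parameter(np.zeros(n_out, dtype=dtype))

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        self.W.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return g @ self.W.value.T


class LayerNorm(Module):
    """Normalization over the last axis with learned gain/bias."""

    def __init__(self, dim: int, dtype=np.float32, eps: float = 1e-5):
        self.g = Parameter(np.ones(dim, dtype=dtype))
        self.b = Parameter(np.zeros(dim, dtype=dtype))
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.g.value * self._xhat + self.b.value

    def backward(self, gout):
        xhat, inv = self._xhat, self._inv
        self.g.grad += (gout * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
        self.b.grad += gout.reshape(-1, gout.shape[-1]).sum(axis=0)
        gx_hat = gout * self.g.value
        m1 = gx_hat.mean(axis=-1, keepdims=True)
        m2 = (gx_hat * xhat).mean(axis=-1, keepdims=True)
        return inv * (gx_hat - m1 - xhat * m2)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Sigmoid(Module):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)


class SiLU(Module):
    """Swish: x * sigmoid(x)."""

    def forward(self, x):
        self._x = x
        self._s = 1.0 / (1.0 + np.exp(-x))
        return x * self._s

    def backward(self, g):
        s = self._s
        return g * s * (1.0 + self._x * (1.0 - s))


class GLU(Module):
    """Gated linear unit splitting the last axis in halves: a * sigmoid(b)."""

    def forward(self, x):
        d = x.shape[-1] // 2
        self._a = x[..., :d]
        self._s = 1.0 / (1.0 + np.exp(-x[..., d:]))
        return self._a * self._s

    def backward(self, g):
        ga = g * self._s
        gb = g * self._a * self._s * (1.0 - self._s)
        return np.concatenate([ga, gb], axis=-1)


class MultiHeadSelfAttention(Module):
    """Scaled-dot-product self-attention over (batch, time, dim)."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 dtype=np.float32):
        if dim % n_heads != 0:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.qkv = Dense(dim, 3 * dim, rng, dtype)
        self.out = Dense(dim, dim, rng, dtype)

    def _split(self, x):
        b, t, _ = x.shape
        return x.reshape(b, t, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge(self, x):
        b, h, t, d = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, t, h * d)

    def forward(self, x):
        qkv = self.qkv.forward(x)
        d = x.shape[-1]
        q = self._split(qkv[..., :d])
        k = self._split(qkv[..., d:2 * d])
        v = self._split(qkv[..., 2 * d:])
        scale = 1.0 / np.sqrt(self.d_head)
        s = (q @ k.transpose(0, 1, 3, 2)) * scale
        s -= s.max(axis=-1, keepdims=True)
        e = np.exp(s)
        a = e / e.sum(axis=-1, keepdims=True)
        o = a @ v
        self._q, self._k, self._v, self._a, self._scale = q, k, v, a, scale
        return self.out.forward(self._merge(o))

    def backward(self, gout):
        go = self._split(self.out.backward(gout))
        a, q, k, v = self._a, self._q, self._k, self._v
        gv = a.transpose(0, 1, 3, 2) @ go
        ga = go @ v.transpose(0, 1, 3, 2)
        gs = a * (ga - (ga * a).sum(axis=-1, keepdims=True))
        gq = (gs @ k) * self._scale
        gk = (gs.transpose(0, 1, 3, 2) @ q) * self._scale
        gqkv = np.concatenate(
            [self._merge(gq), self._merge(gk), self._merge(gv)], axis=-1
        )
        return self.qkv.backward(gqkv)


class DepthwiseConv1d(Module):
    """Per-channel 1-D convolution, 'same' zero padding, odd kernel."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.kernel = kernel
        self.W = Parameter(glorot(rng, (kernel, channels), kernel, kernel, dtype))
        self.b = Parameter(np.zeros(channels, dtype=dtype))

    def forward(self, x):
        b, t, c = x.shape
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        self._xp = xp
        self._tlen = t
        y = np.tile(self.b.value, (b, t, 1))
        for j in range(self.kernel):
            y += xp[:, j : j + t, :] * self.W.value[j]
        return y

    def backward(self, g):
        k, t = self.kernel, self._tlen
        p = k // 2
        xp = self._xp
        self.b.grad += g.sum(axis=(0, 1))
        gxp = np.zeros_like(xp)
        for j in range(k):
            self.W.grad[j] += (xp[:, j : j + t, :] * g).sum(axis=(0, 1))
            gxp[:, j : j + t, :] += g * self.W.value[j]
        return gxp[:, p : p + t, :]


class Conv2d(Module):
    """3x3-style convolution, stride 1, 'same' zero padding, via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k = kernel
        self.c_in, self.c_out = c_in, c_out
        fan = c_in * kernel * kernel
        self.W = Parameter(glorot(rng, (fan, c_out), fan, c_out, dtype))
        self.b = Parameter(np.zeros(c_out, dtype=dtype))

    def forward(self, x):
        bsz, c, h, w = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (b, c, h, w, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(bsz * h * w, c * k * k)
        self._cols = cols
        self._shape = (bsz, c, h, w)
        y = cols @ self.W.value + self.b.value
        return y.reshape(bsz, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, g):
        bsz, c, h, w = self._shape
        k, p = self.k, self.k // 2
        g2 = g.transpose(0, 2, 3, 1).reshape(bsz * h * w, self.c_out)
        self.W.grad += self._cols.T @ g2
        self.b.grad += g2.sum(axis=0)
        gcols = (g2 @ self.W.value.T).reshape(bsz, h, w, c, k, k)
        gxp = np.zeros((bsz, c, h + 2 * p, w + 2 * p), dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + h, j : j + w] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return gxp[:, :, p : p + h, p : p + w]


class ConvTranspose2d(Module):
    """Transposed convolution with kernel 2, stride 2 (exact 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        fan = c_in * 4
        self.W = Parameter(glorot(rng, (c_in, c_out, 2, 2), fan, c_out * 4, dtype))
        self.b = Parameter(np.zeros(c_out, dtype=dtype))

    def forward(self, x):
        self._x = x
        bsz, c, h, w = x.shape
        c_out = self.W.value.shape[1]
        # (b,c,i,j) x (c, d*2*2) -> (b,i,j,d,2,2) -> (b,d,i,2,j,2)
        y = np.tensordot(x, self.W.value.reshape(c, -1), axes=([1], [0]))
        y = y.reshape(bsz, h, w, c_out, 2, 2).transpose(0, 3, 1, 4, 2, 5)
        y = y.reshape(bsz, c_out, 2 * h, 2 * w)
        return y + self.b.value[None, :, None, None]

    def backward(self, g):
        x = self._x
        bsz, c, h, w = x.shape
        c_out = g.shape[1]
        # (b,d,2h,2w) -> (b,i,j,d,2,2) flattened over the last three axes
        gr = (
            g.reshape(bsz, c_out, h, 2, w, 2)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(bsz * h * w, c_out * 4)
        )
        x2 = x.transpose(0, 2, 3, 1).reshape(bsz * h * w, c)
        self.W.grad += (x2.T @ gr).reshape(self.W.value.shape)
        self.b.grad += g.sum(axis=(0, 2, 3))
        gx = gr @ self.W.value.reshape(c, -1).T
        return gx.reshape(bsz, h, w, c).transpose(0, 3, 1, 2)


class MaxPool2d(Module):
    """2x2 max pooling (height and width must be even)."""

    def forward(self, x):
        bsz, c, h, w = x.shape
        xr = x.reshape(bsz, c, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(bsz, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = (bsz, c, h, w)
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, g):
        bsz, c, h, w = self._shape
        gx = np.zeros((bsz, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(gx, self._arg[..., None], g[..., None], axis=-1)
        gx = gx.reshape(bsz, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return gx.reshape(bsz, c, h, w)


class Flatten(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)
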