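"""A compact NumPy neural-network engine for small encoder-decoder CNNs.

Implements exactly the layers the segmentation network needs — 3x3 "same"
convolutions with bias, ReLU, 2x2 max pooling, 2x2 stride-2 transpose
convolutions, channel concatenation, dropout, 1x1 convolutions — each with
an explicit forward/backward pair, plus the Adam optimizer.  Convolutions
are evaluated via im2col and matrix multiplication; transpose convolutions
with stride equal to kernel size reduce to a single einsum (no overlapping
windows).

Arrays are NCHW float32.  All randomness flows through an explicit
``numpy.random.Generator``, so runs are bit-reproducible given a seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


# ---------------------------------------------------------------------------
# im2col helpers
# ---------------------------------------------------------------------------

def im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patches for stride-1 'same' conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, h * w)


def col2im(cols: np.ndarray, x_shape: tuple, k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patches back onto the grid."""
    n, c, h, w = x_shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + h, j:j + w] += cols[:, :, i, j]
    return xp[:, :, pad:pad + h, pad:pad + w]


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    """Base class: parameters, gradients, forward/backward."""

    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """He-uniform initialization for ReLU networks."""
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Conv2d(Layer):
    """k x k stride-1 convolution with zero 'same' padding and bias."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.w = he_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.dw, self.db]

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x, training):
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        if self.k == 1:
            wm = self.w.reshape(self.out_ch, self.in_ch)
            out = np.einsum("oc,nchw->nohw", wm, x, optimize=True)
            out += self.b[None, :, None, None]
            if training:
                self._cache = (x.shape, x)
            return out.astype(DTYPE, copy=False)
        cols = im2col(x, self.k, self.k // 2)
        wm = self.w.reshape(self.out_ch, -1)
        out = np.matmul(wm, cols) + self.b[:, None]
        if training:
            self._cache = (x.shape, cols)
        return out.reshape(n, self.out_ch, h, w)

    def backward(self, grad):
        x_shape, cache = self._cache
        n, _, h, w = x_shape
        g = grad.reshape(n, self.out_ch, h * w)
        self.db[...] = g.sum(axis=(0, 2))
        if self.k == 1:
            x = cache
            self.dw[...] = np.einsum(
                "nohw,nchw->oc", grad, x, optimize=True
            ).reshape(self.w.shape)
            wm = self.w.reshape(self.out_ch, self.in_ch)
            dx = np.einsum("oc,nohw->nchw", wm, grad, optimize=True)
            self._cache = None
            return dx.astype(DTYPE, copy=False)
        cols = cache
        self.dw[...] = np.einsum(
            "nop,nqp->oq", g, cols, optimize=True
        ).reshape(self.w.shape)
        wm = self.w.reshape(self.out_ch, -1)
        dcols = np.matmul(wm.T, g)
        self._cache = None
        return col2im(dcols, x_shape, self.k, self.k // 2)


class ConvTranspose2d(Layer):
    """2x2 stride-2 transpose convolution (learned 2x upsampling) with bias."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.w = he_uniform(rng, (in_ch, out_ch, 2, 2), in_ch)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.dw, self.db]

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x, training):
        n, c, h, w = x.shape
        # stride == kernel: output windows do not overlap
        out = np.einsum("nchw,coij->nohiwj", x, self.w, optimize=True)
        out = out.reshape(n, self.out_ch, 2 * h, 2 * w)
        out += self.b[None, :, None, None]
        if training:
            self._cache = x
        return out.astype(DTYPE, copy=False)

    def backward(self, grad):
        x = self._cache
        n, c, h, w = x.shape
        g = grad.reshape(n, self.out_ch, h, 2, w, 2)
        self.db[...] = grad.sum(axis=(0, 2, 3))
        self.dw[...] = np.einsum("nchw,nohiwj->coij", x, g, optimize=True)
        dx = np.einsum("nohiwj,coij->nchw", g, self.w, optimize=True)
        self._cache = None
        return dx.astype(DTYPE, copy=False)


class ReLU(Layer):
    def forward(self, x, training):
        out = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


class MaxPool2d(Layer):
    """2x2 stride-2 max pooling; gradient routed to the window maxima."""

    def forward(self, x, training):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if training:
            self._cache = (x.shape, xr == out[:, :, :, None, :, None])
        return out

    def backward(self, grad):
        x_shape, winners = self._cache
        n, c, h, w = x_shape
        g = winners * grad[:, :, :, None, :, None]
        self._cache = None
        return g.reshape(n, c, h, w)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the channel axis of NCHW logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
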