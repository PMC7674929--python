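"""Minimal CPU neural-network layers with explicit backward passes.

Convolutions run as im2col + BLAS matmul, which is fast enough for the small
time-frequency inputs this package trains on.  Every layer stores what its
backward pass needs; ``params()`` exposes weight arrays and their gradient
buffers for the optimizer.

All layers accept any float dtype; training uses float32, gradient checks in
the test-suite use float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2x2", "Dropout",
    "Flatten", "Linear", "Sigmoid", "bce_with_logits", "RMSProp",
]


class Param:
    """A weight array with its gradient buffer."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
              dtype) -> np.ndarray:
    """He (Kaiming) normal initialization: std = sqrt(2 / fan_in)."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d:
    """Valid (unpadded) 2-D convolution, stride (s, s)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int], stride: int,
                 rng: np.random.Generator, dtype=np.float32):
        kh, kw = kernel
        fan_in = in_ch * kh * kw
        self.w = Param(he_normal(rng, (out_ch, in_ch, kh, kw), fan_in, dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype))
        self.stride = stride
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        kh, kw = self.w.value.shape[2:]
        s = self.stride
        return (h - kh) // s + 1, (w - kw) // s + 1

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out_ch, in_ch, kh, kw = self.w.value.shape
        s = self.stride
        n, _, h, w = x.shape
        ho, wo = self.out_shape(h, w)
        win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]  # n,c,ho,wo,kh,kw
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, in_ch * kh * kw)
        wmat = self.w.value.reshape(out_ch, -1)
        out = cols @ wmat.T + self.b.value  # n, ho*wo, out_ch
        self._cache = (cols, x.shape)
        return out.transpose(0, 2, 1).reshape(n, out_ch, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        out_ch, in_ch, kh, kw = self.w.value.shape
        s = self.stride
        n, _, ho, wo = dout.shape
        d2 = dout.reshape(n, out_ch, ho * wo).transpose(0, 2, 1)  # n, L, out_ch
        self.w.grad[...] = np.einsum("nlo,nlk->ok", d2, cols).reshape(self.w.value.shape)
        self.b.grad[...] = d2.sum(axis=(0, 1))
        dcols = d2 @ self.w.value.reshape(out_ch, -1)  # n, L, in_ch*kh*kw
        dcols = dcols.reshape(n, ho, wo, in_ch, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        dx = np.zeros(x_shape, dtype=dout.dtype)
        for i in range(kh):
            for j in range(kw):
                dx[:, :, i : i + s * (ho - 1) + 1 : s, j : j + s * (wo - 1) + 1 : s] += \
                    dcols[:, :, :, :, i, j]
        return dx


class BatchNorm2d:
    """Per-feature-map batch normalization with running statistics for eval."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(n_ch, dtype=dtype))
        self.beta = Param(np.zeros(n_ch, dtype=dtype))
        self.running_mean = np.zeros(n_ch, dtype=dtype)
        self.running_var = np.ones(n_ch, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        c = x.shape[1]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * m / max(m - 1, 1)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
        if train:
            self._cache = (xhat, inv)
        return self.gamma.value.reshape(1, c, 1, 1) * xhat + self.beta.value.reshape(1, c, 1, 1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        c = dout.shape[1]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad[...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad[...] = dout.sum(axis=(0, 2, 3))
        g = self.gamma.value.reshape(1, c, 1, 1)
        dxhat = dout * g
        # standard batch-norm backward (batch statistics participate in the graph)
        dx = (inv.reshape(1, c, 1, 1) / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        )
        return dx


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2x2:
    """2×2 max pooling, stride 2, valid: odd trailing rows/cols are dropped."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        xc = x[:, :, : 2 * ho, : 2 * wo]
        blocks = xc.reshape(n, c, ho, 2, wo, 2)
        out = blocks.max(axis=(3, 5))
        mask = blocks == out[:, :, :, None, :, None]
        # break ties deterministically: keep only the first max per block
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
        first = np.cumsum(flat, axis=-1) == 1
        mask = (flat & first).reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._cache = (mask, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask, x_shape = self._cache
        n, c, ho, wo = dout.shape
        dx = np.zeros(x_shape, dtype=dout.dtype)
        dblock = mask * dout[:, :, :, None, :, None]
        dxc = np.zeros((n, c, 2 * ho, 2 * wo), dtype=dout.dtype)
        dxc[:, :, 0::2, 0::2] = dblock[:, :, :, 0, :, 0]
        dxc[:, :, 0::2, 1::2] = dblock[:, :, :, 0, :, 1]
        dxc[:, :, 1::2, 0::2] = dblock[:, :, :, 1, :, 0]
        dxc[:, :, 1::2, 1::2] = dblock[:, :, :, 1, :, 1]
        dx[:, :, : 2 * ho, : 2 * wo] = dxc
        return dx


class Dropout:
    """Inverted dropout: active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Flatten:
    def __init__(self):
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        self.w = Param(he_normal(rng, (n_out, n_in), n_in, dtype))
        self.b = Param(np.zeros(n_out, dtype=dtype))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad[...] = dout.T @ self._x
        self.b.grad[...] = dout.sum(axis=0)
        return dout @ self.w.value


class Sigmoid:
    def __init__(self):
        self._out = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._out * (1.0 - self._out)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw logits; returns (loss, dlogits).

    Numerically stable: loss_i = softplus(z_i) - y_i * z_i.
    """
    z = logits.ravel().astype(np.float64)
    y = y.ravel().astype(np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    dz = ((1.0 / (1.0 + np.exp(-z))) - y) / z.size
    return loss, dz.reshape(logits.shape).astype(logits.dtype)


class RMSProp:
    """RMSProp with momentum and (coupled) weight decay.

    Matches the common deep-learning-framework formulation: the squared-
    gradient running average uses smoothing constant `alpha`; with momentum,
    a velocity buffer accumulates the preconditioned gradient.
    """

    def __init__(self, params: list[Param], lr: float = 5e-4, alpha: float = 0.99,
                 eps: float = 1e-8, momentum: float = 0.9, weight_decay: float = 1e-6):
        self.params = params
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.sq = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self.buf = [np.zeros_like(p.value, dtype=np.float64) for p in params]

    def step(self) -> None:
        for p, sq, buf in zip(self.params, self.sq, self.buf):
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.value.astype(np.float64)
            sq *= self.alpha
            sq += (1.0 - self.alpha) * g * g
            upd = g / (np.sqrt(sq) + self.eps)
            if self.momentum:
                buf *= self.momentum
                buf += upd
                upd = buf
            p.value -= (self.lr * upd).astype(p.value.dtype)
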