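"""Minimal NumPy neural-network layers with hand-written backpropagation.

Implemented in-package so the segmentation network is a plain, dependency
-light NumPy artifact: 2D convolution ("same" padding, im2col + GEMM),
batch normalisation with running statistics, ReLU, 2×2 max pooling, 2×2
stride-2 transposed convolution, inverted dropout, sigmoid, and an Adam
optimiser.  All tensors are NCHW float32.  Each layer caches what its
backward pass needs during forward; ``backward(gy)`` returns the gradient
with respect to the layer input and accumulates parameter gradients.

This is deliberately a small fixed menu — exactly the operations a 2D
U-Net needs — not a general autodiff system.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """A parameter with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> list[Tensor]:
        return []

    def state(self) -> dict[str, np.ndarray]:
        """Non-trainable buffers (e.g. batch-norm running stats)."""
        return {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """k×k convolution with "same" zero padding, stride 1, He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator, name: str = ""):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.k = k
        self.in_ch = in_ch
        self.out_ch = out_ch
        std = np.sqrt(2.0 / (in_ch * k * k))
        self.W = Tensor(rng.normal(0.0, std, (out_ch, in_ch, k, k)), f"{name}.W")
        self.b = Tensor(np.zeros(out_ch), f"{name}.b")
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))  # (N,C,H,W,k,k)
        y = np.tensordot(win, self.W.value, axes=([1, 4, 5], [1, 2, 3]))  # (N,H,W,out)
        y += self.b.value
        self._cache = (x.shape, win)
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, gy):
        x_shape, win = self._cache
        n, c, h, w = x_shape
        p = self.k // 2
        self.W.grad += np.tensordot(gy, win, axes=([0, 2, 3], [0, 2, 3]))
        self.b.grad += gy.sum(axis=(0, 2, 3))
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                # (N,out,H,W) x (out,C) -> (N,C,H,W)
                t = np.tensordot(gy, self.W.value[:, :, i, j], axes=([1], [0]))
                gxp[:, :, i : i + h, j : j + w] += t.transpose(0, 3, 1, 2)
        return gxp[:, :, p : p + h, p : p + w] if p else gxp


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5, name: str = ""):
        self.gamma = Tensor(np.ones(ch), f"{name}.gamma")
        self.beta = Tensor(np.zeros(ch), f"{name}.beta")
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x - mean[:, None, None]) / std[:, None, None]
        self._cache = (xhat, std) if training else None
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, gy):
        xhat, std = self._cache
        m = gy.shape[0] * gy.shape[2] * gy.shape[3]
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        g = self.gamma.value[:, None, None]
        gxhat = gy * g
        # standard batch-norm backward
        t1 = gxhat.sum(axis=(0, 2, 3))[:, None, None]
        t2 = (gxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        return (gxhat - t1 / m - xhat * t2 / m) / std[:, None, None]


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class MaxPool2(Layer):
    """2×2 max pooling, stride 2; input spatial dims must be even."""

    def forward(self, x, training):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        n, c, h, w = self._shape
        gxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(gxr, self._idx[..., None], gy[..., None], axis=-1)
        gxr = gxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return gxr.reshape(n, c, h, w)


class ConvTranspose2(Layer):
    """2×2 transposed convolution with stride 2 (spatial upsampling ×2)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, name: str = ""):
        std = np.sqrt(2.0 / in_ch)
        self.W = Tensor(rng.normal(0.0, std, (in_ch, out_ch, 2, 2)), f"{name}.W")
        self.b = Tensor(np.zeros(out_ch), f"{name}.b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        self._x = x
        t = np.tensordot(x, self.W.value, axes=([1], [0]))  # (N,H,W,out,2,2)
        n, h, w, o, _, _ = t.shape
        y = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, o, 2 * h, 2 * w)
        return y + self.b.value[:, None, None]

    def backward(self, gy):
        n, o, h2, w2 = gy.shape
        h, w = h2 // 2, w2 // 2
        gyt = gy.reshape(n, o, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)  # (N,H,W,out,2,2)
        self.b.grad += gy.sum(axis=(0, 2, 3))
        self.W.grad += np.tensordot(self._x, gyt, axes=([0, 2, 3], [0, 1, 2]))
        gx = np.tensordot(gyt, self.W.value, axes=([3, 4, 5], [1, 2, 3]))  # (N,H,W,in)
        return np.ascontiguousarray(gx.transpose(0, 3, 1, 2))


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class Sigmoid(Layer):
    def forward(self, x, training):
        # numerically stable logistic
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        self._y = y
        return y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


class Adam:
    """Adam optimiser over a flat parameter list."""

    def __init__(self, params: list[Tensor], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad**2 - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
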