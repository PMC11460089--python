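"""Minimal numpy neural-network layers with explicit backpropagation.

Only what the input-function regression model needs: same-padded 3-D and
1-D convolutions, batch normalization, ReLU/softplus, 2x2x2 max pooling,
dense layers, mean-squared-error loss and the Adam optimizer.  All
computation is float32; every layer caches what its backward pass needs.
Weight initialization is He-normal from an explicit generator, so a model
is fully determined by its seed.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = [
    "Param",
    "Conv3dSame",
    "Conv1dSame",
    "BatchNorm",
    "ReLU",
    "Softplus",
    "MaxPool3d",
    "Dense",
    "Adam",
    "mse_loss",
]


class Param:
    """A trainable tensor and its gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv3dSame(Layer):
    """3-D convolution, odd kernel, stride 1, zero same-padding."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        assert k % 2 == 1
        self.k = k
        self.W = Param(_he_normal(rng, (c_out, c_in, k, k, k), c_in * k**3))
        self.b = Param(np.zeros(c_out, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        p = self.k // 2
        self._xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        N, _, D, H, Wd = x.shape
        c_out = self.W.value.shape[0]
        y = np.zeros((N, D, H, Wd, c_out), dtype=np.float32)
        for i, j, l in product(range(self.k), repeat=3):
            patch = self._xp[:, :, i : i + D, j : j + H, l : l + Wd]
            y += np.tensordot(patch, self.W.value[:, :, i, j, l], axes=(1, 1))
        y += self.b.value
        self._shape = x.shape
        return np.ascontiguousarray(np.moveaxis(y, -1, 1))

    def backward(self, gy):
        N, _, D, H, Wd = self._shape
        self.b.grad += gy.sum(axis=(0, 2, 3, 4))
        gxp = np.zeros_like(self._xp)
        for i, j, l in product(range(self.k), repeat=3):
            patch = self._xp[:, :, i : i + D, j : j + H, l : l + Wd]
            self.W.grad[:, :, i, j, l] += np.tensordot(
                gy, patch, axes=([0, 2, 3, 4], [0, 2, 3, 4])
            )
            contrib = np.tensordot(gy, self.W.value[:, :, i, j, l], axes=(1, 0))
            gxp[:, :, i : i + D, j : j + H, l : l + Wd] += np.moveaxis(contrib, -1, 1)
        p = self.k // 2
        return gxp[:, :, p : p + D, p : p + H, p : p + Wd]


class Conv1dSame(Layer):
    """1-D convolution along the last axis, odd kernel, same-padding."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        assert k % 2 == 1
        self.k = k
        self.W = Param(_he_normal(rng, (c_out, c_in, k), c_in * k))
        self.b = Param(np.zeros(c_out, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        p = self.k // 2
        self._xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        N, _, T = x.shape
        self._T = T
        c_out = self.W.value.shape[0]
        y = np.zeros((N, T, c_out), dtype=np.float32)
        for i in range(self.k):
            patch = self._xp[:, :, i : i + T]
            y += np.tensordot(patch, self.W.value[:, :, i], axes=(1, 1))
        y += self.b.value
        return np.ascontiguousarray(np.moveaxis(y, -1, 1))

    def backward(self, gy):
        T = self._T
        self.b.grad += gy.sum(axis=(0, 2))
        gxp = np.zeros_like(self._xp)
        for i in range(self.k):
            patch = self._xp[:, :, i : i + T]
            self.W.grad[:, :, i] += np.tensordot(gy, patch, axes=([0, 2], [0, 2]))
            contrib = np.tensordot(gy, self.W.value[:, :, i], axes=(1, 0))
            gxp[:, :, i : i + T] += np.moveaxis(contrib, -1, 1)
        p = self.k // 2
        return gxp[:, :, p : p + T]


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis (1)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def _bshape(self, ndim):
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x, train=True):
        axes = (0,) + tuple(range(2, x.ndim))
        shp = self._bshape(x.ndim)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x - mean.reshape(shp)) / std.reshape(shp)
        self._cache = (xhat.astype(np.float32), std, axes, shp)
        return self.gamma.value.reshape(shp) * self._cache[0] + self.beta.value.reshape(shp)

    def backward(self, gy):
        xhat, std, axes, shp = self._cache
        m = gy.size // gy.shape[1]
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g = self.gamma.value.reshape(shp)
        gxhat = gy * g
        gx = (
            gxhat
            - gxhat.mean(axis=axes, keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True)
        ) / std.reshape(shp)
        return gx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, gy):
        return np.where(self._mask, gy, 0)


class Softplus(Layer):
    """Smooth non-negative rectifier log(1 + e^x)."""

    def forward(self, x, train=True):
        self._x = x
        return np.logaddexp(0.0, x).astype(np.float32)

    def backward(self, gy):
        sig = 1.0 / (1.0 + np.exp(-self._x))
        return (gy * sig).astype(np.float32)


class MaxPool3d(Layer):
    """2x2x2 max pooling (spatial dims must be even)."""

    def forward(self, x, train=True):
        N, C, D, H, W = x.shape
        assert D % 2 == 0 and H % 2 == 0 and W % 2 == 0, "pooling needs even dims"
        xr = x.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(N, C, D // 2, H // 2, W // 2, 8)
        self._idx = np.argmax(xr, axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        N, C, D, H, W = self._shape
        g = np.zeros((N, C, D // 2, H // 2, W // 2, 8), dtype=np.float32)
        np.put_along_axis(g, self._idx[..., None], gy[..., None], axis=-1)
        g = g.reshape(N, C, D // 2, H // 2, W // 2, 2, 2, 2)
        g = g.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(N, C, D, H, W)
        return g


class Dense(Layer):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator):
        self.W = Param(_he_normal(rng, (f_in, f_out), f_in))
        self.b = Param(np.zeros(f_out, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gy):
        self.W.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.value.T


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. the prediction."""
    diff = (pred - target).astype(np.float32)
    loss = float(np.mean(diff**2))
    return loss, (2.0 / diff.size) * diff


class Adam:
    """Adam with the standard hyperparameters (β1=0.9, β2=0.999, ε=1e-8)."""

    def __init__(self, params: list[Param], lr: float = 2e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
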