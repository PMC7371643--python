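"""Minimal NumPy neural-network engine for small encoder-decoder models.

Implements exactly the layers the segmentation networks need (3x3 conv,
batch normalization, ReLU, 2x2 max-pool, 2x2 stride-2 transposed conv,
1x1 conv, sigmoid) with hand-written backward passes and Adam.  All
computation is float32; convolutions use im2col + GEMM.  The engine is
deterministic: every stochastic choice comes from an explicit Generator.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2", "ConvTranspose2",
    "Sigmoid", "ConvBlock", "Adam", "rmse_loss", "bce_loss",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H+k-1, W+k-1) padded input -> (C*k*k, N*H*W) column matrix."""
    n, c, hp, wp = x.shape
    h, w = hp - k + 1, wp - k + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # (N, C, H, W, k, k) -> (C, k, k, N, H, W)
    cols = win.transpose(1, 4, 5, 0, 2, 3).reshape(c * k * k, n * h * w)
    return np.ascontiguousarray(cols)


class Conv2d:
    """k x k convolution, stride 1, 'same' padding for odd k."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.k, self.cin, self.cout = k, cin, cout
        self.pad = (k - 1) // 2
        self.W = Param(_he_init(rng, (cout, cin * k * k), cin * k * k))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        if self.pad:
            xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        else:
            xp = x
        cols = _im2col(xp, self.k)
        y = (self.W.value @ cols + self.b.value[:, None])
        y = y.reshape(self.cout, n, h, w).transpose(1, 0, 2, 3)
        self._cache = (cols, (n, c, h, w))
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        dyf = np.ascontiguousarray(dy.transpose(1, 0, 2, 3)).reshape(self.cout, -1)
        self.W.grad += dyf @ cols.T
        self.b.grad += dyf.sum(axis=1)
        dcols = self.W.value.T @ dyf  # (C*k*k, N*H*W)
        dxp = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad), dtype=np.float32)
        dcols = dcols.reshape(c, self.k, self.k, n, h, w)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, i, j].transpose(1, 0, 2, 3)
        if self.pad:
            return dxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dxp


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape, training)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape, training = self._cache
        n_eff = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not training:
            return dy * g * inv[None, :, None, None]
        dxhat = dy * g
        term = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / n_eff)
        return term * inv[None, :, None, None]


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2:
    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        self._cache = (xr, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xr, y = self._cache
        mask = xr == y[:, :, :, None, :, None]
        dxr = mask * dy[:, :, :, None, :, None]
        n, c, h2, _, w2, _ = xr.shape
        return dxr.reshape(n, c, h2 * 2, w2 * 2)


class ConvTranspose2:
    """2x2 transposed convolution with stride 2 (exact upsampling by 2)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        self.W = Param(_he_init(rng, (cin, cout, 2, 2), cin))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        self._x = x
        y = np.einsum("nchw,cdab->ndhawb", x, self.W.value)
        y = y.reshape(n, self.cout, 2 * h, 2 * w)
        return y + self.b.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, d, h2, w2 = dy.shape
        dyr = dy.reshape(n, d, h2 // 2, 2, w2 // 2, 2)  # (n,d,h,a,w,b)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        self.W.grad += np.einsum("nchw,ndhawb->cdab", self._x, dyr)
        return np.einsum("ndhawb,cdab->nchw", dyr, self.W.value)


class Sigmoid:
    def __init__(self):
        self._y = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class ConvBlock:
    """[3x3 conv -> batchnorm -> ReLU] x 2."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.layers = [
            Conv2d(cin, cout, 3, rng), BatchNorm2d(cout), ReLU(),
            Conv2d(cout, cout, 3, rng), BatchNorm2d(cout), ReLU(),
        ]

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * p.grad
            v[...] = self.beta2 * v + (1 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def rmse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Root of the mean squared error over every pixel and channel of the batch."""
    diff = pred - target
    mse = float(np.mean(diff ** 2))
    rmse = np.sqrt(mse)
    if rmse == 0.0:
        return 0.0, np.zeros_like(pred)
    grad = diff / (diff.size * rmse)
    return rmse, grad.astype(np.float32)


def bce_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Pixel-wise binary cross-entropy against a binary label map."""
    eps = 1e-7
    p = np.clip(pred, eps, 1.0 - eps)
    loss = float(np.mean(-(target * np.log(p) + (1.0 - target) * np.log(1.0 - p))))
    grad = ((p - target) / (p * (1.0 - p))) / p.size
    return loss, grad.astype(np.float32)
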