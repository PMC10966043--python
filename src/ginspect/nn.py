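"""Minimal numpy neural-network layers used by the classifier.

Channel-last layout throughout (images are ``N x H x W x C``).  Each layer
implements ``forward(x, training)`` and ``backward(grad)``; trainable arrays
and their gradients are exposed through ``params_grads`` for the optimizer.
Parameter counting follows the common bookkeeping where batch normalization
contributes four values per channel (scale, shift, and the two moving
statistics).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ModelSpecError

#: Network-internal dtype; single precision keeps the conv layers within the
#: memory bandwidth of one core without affecting classification results.
DTYPE = np.float32


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def mae(target: np.ndarray, predicted: np.ndarray) -> float:
    """Mean absolute error between a target encoding and a prediction,
    averaged over every vector entry."""
    target = np.asarray(target, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if target.shape != predicted.shape:
        raise ModelSpecError(
            f"target shape {target.shape} != predicted shape {predicted.shape}"
        )
    return float(np.abs(target - predicted).mean())


def mae_softmax_grad(target: np.ndarray, logits: np.ndarray) -> tuple[float, np.ndarray]:
    """MAE loss on softmax probabilities and its gradient w.r.t. the logits."""
    p = softmax(logits)
    loss = mae(target, p)
    target = np.asarray(target, dtype=p.dtype)
    g = np.sign(p - target) / target.size  # dL/dp
    # backprop through softmax: dL/dz = p * (g - <g, p>)
    gz = p * (g - (g * p).sum(axis=-1, keepdims=True))
    return loss, gz


class Layer:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params_grads(self):
        """Yield (param, grad) array pairs for trainable parameters."""
        return ()

    @property
    def param_count(self) -> int:
        """Total stored parameters (including non-trainable statistics)."""
        return sum(p.size for p, _ in self.params_grads())


class Dense(Layer):
    """Fully connected layer with bias, optional ReLU."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, relu: bool = True):
        if n_in < 1 or n_out < 1:
            raise ModelSpecError(f"dense layer dims must be positive, got {n_in}x{n_out}")
        scale = np.sqrt(2.0 / n_in) if relu else np.sqrt(1.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.relu = relu

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=DTYPE)
        self._x = x
        z = x @ self.W + self.b
        if self.relu:
            self._mask = z > 0
            return z * self._mask
        return z

    def backward(self, grad):
        if self.relu:
            grad = grad * self._mask
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params_grads(self):
        yield self.W, self.dW
        yield self.b, self.db


class Conv3x3(Layer):
    """3x3 convolution, stride 1, same padding (no activation).

    Implemented as one im2col matrix product per pass so the heavy lifting is
    a single BLAS call.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        if c_in < 1 or c_out < 1:
            raise ModelSpecError("conv channel counts must be positive")
        scale = np.sqrt(2.0 / (9 * c_in))
        self.W = rng.normal(0.0, scale, size=(3, 3, c_in, c_out)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=DTYPE)
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # n,h,w,c,3,3
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * w, 9 * c)
        self._cols = cols
        self._shape = (n, h, w, c)
        co = self.W.shape[3]
        out = cols @ self.W.reshape(9 * c, co)
        out += self.b
        return out.reshape(n, h, w, co)

    def backward(self, grad):
        n, h, w, c = self._shape
        co = self.W.shape[3]
        g2 = np.ascontiguousarray(grad, dtype=DTYPE).reshape(-1, co)
        self.db[...] = g2.sum(axis=0)
        self.dW[...] = (self._cols.T @ g2).reshape(3, 3, c, co)
        dcols = (g2 @ self.W.reshape(9 * c, co).T).reshape(n, h, w, 3, 3, c)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=DTYPE)
        for di in range(3):
            for dj in range(3):
                dxp[:, di : di + h, dj : dj + w, :] += dcols[:, :, :, di, dj, :]
        return dxp[:, 1 : h + 1, 1 : w + 1, :]

    def params_grads(self):
        yield self.W, self.dW
        yield self.b, self.db


class BatchNorm(Layer):
    """Channel-wise batch normalization (four stored values per channel:
    gamma, beta and the moving mean/variance)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.dgamma = np.zeros(channels, dtype=DTYPE)
        self.dbeta = np.zeros(channels, dtype=DTYPE)
        self.moving_mean = np.zeros(channels, dtype=DTYPE)
        self.moving_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._first = True

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            if self._first:
                self.moving_mean[...] = mu
                self.moving_var[...] = var
                self._first = False
            else:
                m = self.momentum
                self.moving_mean[...] = m * self.moving_mean + (1 - m) * mu
                self.moving_var[...] = m * self.moving_var + (1 - m) * var
        else:
            mu = self.moving_mean
            var = self.moving_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if training:
            self._xhat = xhat
            self._inv = inv
            self._m = x.size // x.shape[-1]
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        axes = tuple(range(grad.ndim - 1))
        self.dgamma[...] = (grad * self._xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        m = self._m
        # dx = gamma*inv * (grad - dbeta/m - xhat*dgamma/m), fused in-place
        out = grad - self.dbeta / m
        out -= self._xhat * (self.dgamma / m)
        out *= self.gamma * self._inv
        return out

    def params_grads(self):
        yield self.gamma, self.dgamma
        yield self.beta, self.dbeta

    @property
    def param_count(self) -> int:
        # gamma + beta + moving mean + moving variance
        return 4 * self.gamma.size


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, DTYPE(0))

    def backward(self, grad):
        grad = np.asarray(grad)
        grad *= self._mask
        return grad


class MaxPool2(Layer):
    """2x2 max pooling, stride 2.  Gradient goes to the first maximum of each
    window (deterministic under ties)."""

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ModelSpecError(f"pooling needs even spatial dims, got {h}x{w}")
        self._quads = (
            x[:, 0::2, 0::2], x[:, 0::2, 1::2], x[:, 1::2, 0::2], x[:, 1::2, 1::2]
        )
        a, b, cq, d = self._quads
        out = np.maximum(np.maximum(a, b), np.maximum(cq, d))
        self._out = out
        self._shape = (n, h, w, c)
        return out

    def backward(self, grad):
        n, h, w, c = self._shape
        dx = np.zeros((n, h, w, c), dtype=DTYPE)
        taken = np.zeros(grad.shape, dtype=bool)
        views = (dx[:, 0::2, 0::2], dx[:, 0::2, 1::2], dx[:, 1::2, 0::2], dx[:, 1::2, 1::2])
        for quad, view in zip(self._quads, views):
            hit = (quad == self._out) & ~taken  # first maximum wins
            view[hit] = grad[hit]
            taken |= hit
        return dx


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ModelSpecError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = self.rng.random(x.shape, dtype=np.float32) >= self.rate
        self._mask = keep.astype(DTYPE) / DTYPE(1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params_grads(self):
        for layer in self.layers:
            yield from layer.params_grads()

    @property
    def param_count(self) -> int:
        return sum(layer.param_count for layer in self.layers)


class Adam:
    """Adam optimizer over (param, grad) array pairs."""

    def __init__(self, params_grads, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.slots = [(p, g, np.zeros_like(p), np.zeros_like(p)) for p, g in params_grads]
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, g, m, v in self.slots:
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
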