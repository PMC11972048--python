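"""Minimal CPU neural-network layers with explicit backpropagation.

All layers operate on ``float32`` arrays in channels-last layout:
dense inputs are ``(N, C)``, volumetric inputs are ``(N, D, H, W, C)``.
Each layer owns its trainable :class:`Param` objects; gradient arrays are
accumulated on the params by :meth:`backward` and consumed by an optimizer.

Spatial layers use "same" padding with the TensorFlow convention, so a
stride-2 layer maps an axis of length ``n`` to ``ceil(n / 2)``.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

F32 = np.float32


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    """Base layer: ``forward`` caches what ``backward`` needs."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _same_pad(n: int, k: int, s: int) -> tuple[int, int, int]:
    out = -(-n // s)
    pad = max((out - 1) * s + k - n, 0)
    return out, pad // 2, pad - pad // 2


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "dense"):
        scale = math.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, size=(n_in, n_out)), f"{name}.w")
        self.b = Param(np.zeros(n_out), f"{name}.b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Conv3D(Layer):
    """3-D convolution, kernel ``k^3``, "same" padding, cubic stride."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int,
                 rng: np.random.Generator, name: str = "conv",
                 input_grad: bool = True):
        fan_in = k ** 3 * c_in
        scale = math.sqrt(2.0 / fan_in)
        self.w = Param(rng.normal(0.0, scale, size=(k, k, k, c_in, c_out)), f"{name}.w")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self.k, self.s, self.c_in, self.c_out = k, stride, c_in, c_out
        self.input_grad = input_grad        # first layers may skip col2im

    def params(self):
        return [self.w, self.b]

    def _windows(self, x):
        n, d, h, w, c = x.shape
        k, s = self.k, self.s
        (do, pd0, pd1) = _same_pad(d, k, s)
        (ho, ph0, ph1) = _same_pad(h, k, s)
        (wo, pw0, pw1) = _same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (pd0, pd1), (ph0, ph1), (pw0, pw1), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        win = win[:, ::s, ::s, ::s]                      # (N,Do,Ho,Wo,C,k,k,k) view
        return win, (do, ho, wo), xp.shape, (pd0, ph0, pw0)

    def forward(self, x, training=False):
        self._in_shape = x.shape
        win, (do, ho, wo), self._xp_shape, self._pads = self._windows(x)
        if not training:
            # contract window and channel axes against the kernel in place
            self._cols = None
            y = np.tensordot(win, self.w.value, axes=([5, 6, 7, 4], [0, 1, 2, 3]))
            return (y + self.b.value).astype(F32, copy=False)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 3, 5, 6, 7, 4))
        cols = cols.reshape(-1, self.k ** 3 * self.c_in)
        self._cols = cols
        y = cols @ self.w.value.reshape(-1, self.c_out) + self.b.value
        return y.reshape(x.shape[0], do, ho, wo, self.c_out)

    def backward(self, dy):
        n, do, ho, wo, _ = dy.shape
        k, s = self.k, self.s
        dy2 = dy.reshape(-1, self.c_out)
        self.w.grad += (self._cols.T @ dy2).reshape(self.w.value.shape)
        self.b.grad += dy2.sum(axis=0)
        if not self.input_grad:
            return None
        dcols = np.tensordot(dy, self.w.value, axes=([4], [4]))  # (N,Do,Ho,Wo,k,k,k,C)
        dxp = np.zeros(self._xp_shape, dtype=F32)
        for i, j, l in itertools.product(range(k), range(k), range(k)):
            dxp[:, i:i + s * do:s, j:j + s * ho:s, l:l + s * wo:s, :] += dcols[:, :, :, :, i, j, l, :]
        pd0, ph0, pw0 = self._pads
        _, d, h, w, _ = self._in_shape
        return dxp[:, pd0:pd0 + d, ph0:ph0 + h, pw0:pw0 + w, :]


class MaxPool3D(Layer):
    """Max pooling, window ``k^3``, "same" padding."""

    def __init__(self, k: int = 3, stride: int = 2):
        self.k, self.s = k, stride

    def forward(self, x, training=False):
        n, d, h, w, c = x.shape
        k, s = self.k, self.s
        (do, pd0, pd1) = _same_pad(d, k, s)
        (ho, ph0, ph1) = _same_pad(h, k, s)
        (wo, pw0, pw1) = _same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (pd0, pd1), (ph0, ph1), (pw0, pw1), (0, 0)),
                    constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        win = win[:, ::s, ::s, ::s]                      # (N,Do,Ho,Wo,C,k,k,k)
        flat = win.reshape(n, do, ho, wo, c, k ** 3)
        self._arg = flat.argmax(axis=-1)
        self._meta = (x.shape, xp.shape, (pd0, ph0, pw0), (do, ho, wo))
        return flat.max(axis=-1)

    def backward(self, dy):
        in_shape, xp_shape, (pd0, ph0, pw0), (do, ho, wo) = self._meta
        k, s = self.k, self.s
        dxp = np.zeros(xp_shape, dtype=F32)
        for idx, (i, j, l) in enumerate(itertools.product(range(k), range(k), range(k))):
            mask = self._arg == idx
            if not mask.any():
                continue
            contrib = np.where(mask, dy, 0).transpose(0, 1, 2, 3, 4)
            dxp[:, i:i + s * do:s, j:j + s * ho:s, l:l + s * wo:s, :] += contrib
        _, d, h, w, _ = in_shape
        return dxp[:, pd0:pd0 + d, ph0:ph0 + h, pw0:pw0 + w, :]


class BatchNorm(Layer):
    """Batch normalization over all non-channel axes (channels-last).

    Trainable scale/shift only count as parameters; running moments are
    buffers used at evaluation time.
    """

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-3, name: str = "bn"):
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.run_mean = np.zeros(c, dtype=F32)
        self.run_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (self.momentum * self.run_mean + (1 - self.momentum) * mean).astype(F32)
            self.run_var = (self.momentum * self.run_var + (1 - self.momentum) * var).astype(F32)
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * inv
        self._inv = inv
        self._m = x.size // x.shape[-1]
        self._training = training
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.gamma.grad += (dy * self._xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        if not self._training:
            return dy * self.gamma.value * self._inv
        m = self._m
        dxhat = dy * self.gamma.value
        term = dxhat - dxhat.mean(axis=axes) - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        return term * self._inv


class GlobalAvgPool(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, dy):
        n, d, h, w, c = self._shape
        scale = 1.0 / (d * h * w)
        return np.broadcast_to(dy[:, None, None, None, :] * scale, self._shape).astype(F32)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x, training=False):
        for lay in self.layers:
            x = lay.forward(x, training=training)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy
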