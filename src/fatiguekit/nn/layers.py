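"""Layers with forward/backward passes.

Conventions: convolutional tensors are (batch, channels, length); dense
tensors are (batch, features).  Every layer caches what its backward pass
needs during forward; ``backward`` consumes the upstream gradient and
returns the gradient with respect to the layer input while accumulating
parameter gradients in ``Param.grad``.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its gradient with respect to the logits."""
    p = softmax(logits)
    n = len(y)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n, p


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def conv_output_length(length: int, stride: int) -> int:
    """Same-padding 1-D convolution output length: ceil(length / stride)."""
    return -(-length // stride)


def pool_output_length(length: int, pool_stride: int) -> int:
    """Non-padded pooling output length: floor(length / pool_stride)."""
    return length // pool_stride


class Conv1D(Layer):
    """Same-padded strided 1-D convolution."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, rng: np.random.Generator | None = None):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / (in_channels * kernel))
        self.w = Param(rng.standard_normal((out_channels, in_channels, kernel))
                       * scale, "conv.w")
        self.b = Param(np.zeros(out_channels), "conv.b")

    def params(self):
        return [self.w, self.b]

    def output_length(self, length: int) -> int:
        return conv_output_length(length, self.stride)

    def forward(self, x, training):
        n, c, length = x.shape
        k, s = self.kernel, self.stride
        l_out = conv_output_length(length, s)
        pad_total = max((l_out - 1) * s + k - length, 0)
        pl = pad_total // 2
        pr = pad_total - pl
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        win = sliding_window_view(xp, k, axis=2)[:, :, ::s, :]
        self._cache = (win, x.shape, pl, pad_total)
        return np.einsum("nilk,oik->nol", win, self.w.value,
                         optimize=True) + self.b.value[None, :, None]

    def backward(self, gy):
        win, x_shape, pl, pad_total = self._cache
        self.w.grad += np.einsum("nol,nilk->oik", gy, win, optimize=True)
        self.b.grad += gy.sum(axis=(0, 2))
        n, c, length = x_shape
        k, s = self.kernel, self.stride
        l_out = gy.shape[2]
        gx_pad = np.zeros((n, c, length + pad_total))
        idx = np.arange(l_out) * s
        for j in range(k):
            contrib = np.einsum("nol,oi->nil", gy, self.w.value[:, :, j],
                                optimize=True)
            gx_pad[:, :, idx + j] += contrib
        return gx_pad[:, :, pl: pl + length]


class MaxPool1D(Layer):
    """Max pooling with pool size == stride (remainder samples dropped)."""

    def __init__(self, pool: int = 2, stride: int | None = None):
        if stride is not None and stride != pool:
            raise ValueError("only pool == stride supported")
        self.pool = pool

    def output_length(self, length: int) -> int:
        return pool_output_length(length, self.pool)

    def forward(self, x, training):
        n, c, length = x.shape
        p = self.pool
        l_out = length // p
        xt = x[:, :, : l_out * p].reshape(n, c, l_out, p)
        self._arg = xt.argmax(axis=3)
        self._shape = x.shape
        return xt.max(axis=3)

    def backward(self, gy):
        n, c, length = self._shape
        p = self.pool
        l_out = gy.shape[2]
        gx = np.zeros((n, c, l_out, p))
        ni, ci, li = np.ogrid[:n, :c, :l_out]
        gx[ni, ci, li, self._arg] = gy
        out = np.zeros((n, c, length))
        out[:, :, : l_out * p] = gx.reshape(n, c, l_out * p)
        return out


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, training, x.shape)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, gy):
        xhat, inv, training, shape = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2))
        self.beta.grad += gy.sum(axis=(0, 2))
        g = self.gamma.value[None, :, None]
        if not training:
            return gy * g * inv[None, :, None]
        m = shape[0] * shape[2]
        gxhat = gy * g
        return (inv[None, :, None] / m) * (
            m * gxhat
            - gxhat.sum(axis=(0, 2), keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=(0, 2), keepdims=True))


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / n_in)
        self.w = Param(rng.standard_normal((n_in, n_out)) * scale, "dense.w")
        self.b = Param(np.zeros(n_out), "dense.b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, gy):
        self.w.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.w.value.T


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.2):
        self.negative_slope = negative_slope

    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, self.negative_slope * x)

    def backward(self, gy):
        return np.where(self._mask, gy, self.negative_slope * gy)


class Sigmoid(Layer):
    def forward(self, x, training):
        self._y = sigmoid(x)
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


def t2f(x: np.ndarray, a, delta, alpha) -> np.ndarray:
    """Interval type-2 fuzzy rectifying unit (functional form).

    ``y = x * [alpha * sigma(a (1+delta) x) + (1-alpha) * sigma(a (1-delta) x)]``

    The two logistic memberships bound the footprint of uncertainty of width
    ``2 a delta |x|``; ``alpha`` blends the upper and lower memberships.  At
    ``delta = 0`` the unit is exactly the swish ``x * sigma(a x)`` for any
    blend, and as ``a`` grows it approaches the rectifier.
    """
    a = np.asarray(a, dtype=float)
    delta = np.asarray(delta, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    upper = sigmoid(a * (1 + delta) * x)
    lower = sigmoid(a * (1 - delta) * x)
    return x * (alpha * upper + (1 - alpha) * lower)


class T2FActivation(Layer):
    """Learnable T2F unit: 3 scalars (slope, FOU width, blend) per channel.

    Ranges are enforced by smooth reparameterization — ``a = exp(a~)``,
    ``delta = 0.99 sigma(d~)``, ``alpha = sigma(al~)`` — so unconstrained
    optimizers can never leave the valid region.  For a layer with C
    channels this adds exactly 3C learnable parameters.
    """

    def __init__(self, channels: int, channel_axis: int = 1):
        self.channels = channels
        self.channel_axis = channel_axis
        self.a_raw = Param(np.zeros(channels), "t2f.a")
        self.d_raw = Param(np.zeros(channels), "t2f.delta")
        self.al_raw = Param(np.zeros(channels), "t2f.alpha")

    def params(self):
        return [self.a_raw, self.d_raw, self.al_raw]

    @property
    def a(self):
        return np.exp(self.a_raw.value)

    @property
    def delta(self):
        return 0.99 * sigmoid(self.d_raw.value)

    @property
    def alpha(self):
        return sigmoid(self.al_raw.value)

    def _bshape(self, ndim):
        shape = [1] * ndim
        axis = self.channel_axis if self.channel_axis >= 0 else ndim + self.channel_axis
        shape[axis] = self.channels
        return tuple(shape)

    def forward(self, x, training):
        bs = self._bshape(x.ndim)
        a = self.a.reshape(bs)
        d = self.delta.reshape(bs)
        al = self.alpha.reshape(bs)
        s1 = sigmoid(a * (1 + d) * x)
        s2 = sigmoid(a * (1 - d) * x)
        self._cache = (x, a, d, al, s1, s2, bs)
        return x * (al * s1 + (1 - al) * s2)

    def backward(self, gy):
        x, a, d, al, s1, s2, bs = self._cache
        ds1 = s1 * (1 - s1)
        ds2 = s2 * (1 - s2)
        mix = al * s1 + (1 - al) * s2
        gx = gy * (mix + x * (al * ds1 * a * (1 + d)
                              + (1 - al) * ds2 * a * (1 - d)))
        sum_axes = tuple(i for i in range(gy.ndim)
                         if bs[i] == 1)
        x2 = x * x
        g_a = (gy * x2 * (al * ds1 * (1 + d) + (1 - al) * ds2 * (1 - d))
               ).sum(axis=sum_axes)
        g_d = (gy * a * x2 * (al * ds1 - (1 - al) * ds2)).sum(axis=sum_axes)
        g_al = (gy * x * (s1 - s2)).sum(axis=sum_axes)
        # chain through the reparameterizations
        sd = sigmoid(self.d_raw.value)
        sal = sigmoid(self.al_raw.value)
        self.a_raw.grad += g_a * np.exp(self.a_raw.value)
        self.d_raw.grad += g_d * 0.99 * sd * (1 - sd)
        self.al_raw.grad += g_al * sal * (1 - sal)
        return gx


class Sequential:
    """A feed-forward stack with shared dropout randomness control."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def seed_dropout(self, seed: int) -> None:
        ss = np.random.SeedSequence(seed)
        drops = [l for l in self.layers if isinstance(l, Dropout)]
        for layer, child in zip(drops, ss.spawn(max(len(drops), 1))):
            layer.rng = np.random.default_rng(child)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0
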