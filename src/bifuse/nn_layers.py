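"""Minimal convolutional layer stack with explicit backpropagation.

Layers operate on 4-D arrays shaped (batch, feature maps, spatial rows,
time samples).  Every layer implements ``forward(x, train, rng)`` and
``backward(grad_out)``; trainable arrays live in :class:`Param` objects so
an optimizer can walk ``layer.params()``.

Conventions: convolutions use cross-correlation with 'same' padding along
the time axis (left pad ``(k-1)//2``); average pools are non-overlapping
and truncate remainders; dropout is inverted (activations scaled at train
time, identity at inference).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


def _uniform_fan_in(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator,
                    dtype) -> np.ndarray:
    bound = float(np.sqrt(1.0 / max(fan_in, 1)))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Layer:
    """Base class; layers without parameters inherit the defaults."""

    def params(self) -> list[Param]:
        return []

    def n_stats(self) -> int:
        """Non-trainable statistics (batch-norm running moments)."""
        return 0

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - interface
        raise NotImplementedError

    def out_shape(self, shape: tuple[int, int, int]) -> tuple[int, int, int]:
        """Propagate an unbatched (maps, rows, samples) shape."""
        return shape


def _same_pad(k: int) -> tuple[int, int]:
    pl = (k - 1) // 2
    return pl, k - 1 - pl


class TemporalConv(Layer):
    """Full convolution over input maps with a (1, k) kernel, same padding.

    Implemented as im2col + GEMM for throughput.
    """

    def __init__(self, in_maps: int, filters: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.in_maps, self.filters, self.k = in_maps, filters, k
        self.w = Param(_uniform_fan_in((filters, in_maps, k), in_maps * k, rng, dtype))

    def params(self):
        return [self.w]

    def forward(self, x, train=False, rng=None):
        pl, pr = _same_pad(self.k)
        b, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (pl, pr)))
        xw = sliding_window_view(xp, self.k, axis=-1)  # (b, c, h, w, k)
        self._cols = np.ascontiguousarray(xw.transpose(0, 2, 3, 1, 4)).reshape(
            b * h * w, c * self.k
        )
        wmat = self.w.value.reshape(self.filters, c * self.k)
        y = self._cols @ wmat.T  # (bhw, f)
        self._bhw = (b, h, w)
        return np.ascontiguousarray(
            y.reshape(b, h, w, self.filters).transpose(0, 3, 1, 2)
        )

    def backward(self, gy):
        pl, pr = _same_pad(self.k)
        b, h, w = self._bhw
        c, k, f = self.in_maps, self.k, self.filters
        g2 = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(b * h * w, f)
        self.w.grad += (g2.T @ self._cols).reshape(f, c, k)
        if getattr(self, "is_input_layer", False):
            return None
        gp = np.pad(gy, ((0, 0), (0, 0), (0, 0), (k - 1 - pl, k - 1 - pr)))
        gw = sliding_window_view(gp, k, axis=-1)  # (b, f, h, w, k)
        gcols = np.ascontiguousarray(gw.transpose(0, 2, 3, 1, 4)).reshape(
            b * h * w, f * k
        )
        wflip = np.ascontiguousarray(self.w.value[..., ::-1])  # (f, c, k)
        wmat = wflip.transpose(0, 2, 1).reshape(f * k, c)
        gx = gcols @ wmat  # (bhw, c)
        return np.ascontiguousarray(gx.reshape(b, h, w, c).transpose(0, 3, 1, 2))

    def out_shape(self, shape):
        c, h, w = shape
        if c != self.in_maps:
            raise ValueError(f"temporal conv expects {self.in_maps} maps, got {c}")
        return (self.filters, h, w)


class DepthwiseSpatial(Layer):
    """Per-map convolution with an (H, 1) kernel collapsing the row axis."""

    def __init__(self, in_maps: int, rows: int, multiplier: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.in_maps, self.rows, self.multiplier = in_maps, rows, multiplier
        self.w = Param(_uniform_fan_in((in_maps, multiplier, rows), rows, rng, dtype))

    def params(self):
        return [self.w]

    def forward(self, x, train=False, rng=None):
        self._x = x
        y = np.einsum("bchw,cmh->bcmw", x, self.w.value, optimize=True)
        b, c, m, w = y.shape
        return y.reshape(b, c * m, 1, w)

    def backward(self, gy):
        b = gy.shape[0]
        gyr = gy.reshape(b, self.in_maps, self.multiplier, -1)
        self.w.grad += np.einsum("bchw,bcmw->cmh", self._x, gyr, optimize=True)
        return np.einsum("bcmw,cmh->bchw", gyr, self.w.value, optimize=True)

    def out_shape(self, shape):
        c, h, w = shape
        if c != self.in_maps or h != self.rows:
            raise ValueError(
                f"depthwise spatial conv expects ({self.in_maps}, {self.rows}, *), "
                f"got {shape}"
            )
        return (self.in_maps * self.multiplier, 1, w)


class DepthwiseTemporal(Layer):
    """Per-map convolution with a (1, k) kernel, same padding."""

    def __init__(self, in_maps: int, multiplier: int, k: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.in_maps, self.multiplier, self.k = in_maps, multiplier, k
        self.w = Param(_uniform_fan_in((in_maps, multiplier, k), k, rng, dtype))

    def params(self):
        return [self.w]

    def forward(self, x, train=False, rng=None):
        pl, pr = _same_pad(self.k)
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (pl, pr)))
        self._xw = sliding_window_view(xp, self.k, axis=-1)
        y = np.einsum("bchwk,cmk->bcmhw", self._xw, self.w.value, optimize=True)
        b, c, m, h, w = y.shape
        return y.reshape(b, c * m, h, w)

    def backward(self, gy):
        pl, pr = _same_pad(self.k)
        b, _, h, w = gy.shape
        gyr = gy.reshape(b, self.in_maps, self.multiplier, h, w)
        self.w.grad += np.einsum("bchwk,bcmhw->cmk", self._xw, gyr, optimize=True)
        gp = np.pad(gyr, ((0, 0), (0, 0), (0, 0), (0, 0),
                          (self.k - 1 - pl, self.k - 1 - pr)))
        gw = sliding_window_view(gp, self.k, axis=-1)
        wflip = self.w.value[..., ::-1]
        return np.einsum("bcmhwk,cmk->bchw", gw, wflip, optimize=True)

    def out_shape(self, shape):
        c, h, w = shape
        if c != self.in_maps:
            raise ValueError(f"depthwise temporal conv expects {self.in_maps} maps, got {c}")
        return (self.in_maps * self.multiplier, h, w)


class Pointwise(Layer):
    """1x1 convolution mixing feature maps."""

    def __init__(self, in_maps: int, out_maps: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.in_maps, self.out_maps = in_maps, out_maps
        self.w = Param(_uniform_fan_in((out_maps, in_maps), in_maps, rng, dtype))

    def params(self):
        return [self.w]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return np.einsum("bchw,oc->bohw", x, self.w.value, optimize=True)

    def backward(self, gy):
        self.w.grad += np.einsum("bchw,bohw->oc", self._x, gy, optimize=True)
        return np.einsum("bohw,oc->bchw", gy, self.w.value, optimize=True)

    def out_shape(self, shape):
        c, h, w = shape
        if c != self.in_maps:
            raise ValueError(f"pointwise conv expects {self.in_maps} maps, got {c}")
        return (self.out_maps, h, w)


class BatchNorm(Layer):
    """Batch normalization over (batch, rows, samples) per feature map."""

    def __init__(self, maps: int, momentum: float = 0.1, eps: float = 1e-3,
                 dtype=np.float32):
        self.maps, self.momentum, self.eps = maps, momentum, eps
        self.gamma = Param(np.ones(maps, dtype=dtype))
        self.beta = Param(np.zeros(maps, dtype=dtype))
        self.running_mean = np.zeros(maps, dtype=dtype)
        self.running_var = np.ones(maps, dtype=dtype)

    def params(self):
        return [self.gamma, self.beta]

    def n_stats(self):
        return self.running_mean.size + self.running_var.size

    def forward(self, x, train=False, rng=None):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        self._train = train
        return (self.gamma.value[None, :, None, None] * self._xhat
                + self.beta.value[None, :, None, None])

    def backward(self, gy):
        axes = (0, 2, 3)
        self.gamma.grad += (gy * self._xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g = self.gamma.value[None, :, None, None]
        if not self._train:
            return gy * g / self._std[None, :, None, None]
        n = gy.shape[0] * gy.shape[2] * gy.shape[3]
        gxhat = gy * g
        term = (gxhat - gxhat.mean(axis=axes, keepdims=True)
                - self._xhat * (gxhat * self._xhat).mean(axis=axes, keepdims=True))
        return term / self._std[None, :, None, None]


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, train=False, rng=None):
        neg = x < 0
        y = np.where(neg, self.alpha * np.expm1(np.clip(x, None, 0.0)), x)
        self._neg, self._y = neg, y
        return y

    def backward(self, gy):
        return gy * np.where(self._neg, self._y + self.alpha, 1.0)


class AvgPool(Layer):
    """Non-overlapping average pool of length p along time, truncating."""

    def __init__(self, p: int):
        if p < 1:
            raise ValueError("pool length must be >= 1")
        self.p = p

    def forward(self, x, train=False, rng=None):
        self._in_w = x.shape[-1]
        n = self._in_w // self.p
        xt = x[..., : n * self.p]
        return xt.reshape(*x.shape[:-1], n, self.p).mean(axis=-1)

    def backward(self, gy):
        g = np.repeat(gy, self.p, axis=-1) / self.p
        pad = self._in_w - g.shape[-1]
        if pad:
            g = np.pad(g, ((0, 0),) * (g.ndim - 1) + ((0, pad),))
        return g

    def out_shape(self, shape):
        c, h, w = shape
        return (c, h, w // self.p)


class Dropout(Layer):
    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)

    def out_shape(self, shape):
        c, h, w = shape
        return (c * h * w, 1, 1)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = False, dtype=np.float32):
        self.in_features, self.out_features = in_features, out_features
        self.w = Param(_uniform_fan_in((out_features, in_features), in_features, rng, dtype))
        self.b = Param(np.zeros(out_features, dtype=dtype)) if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False, rng=None):
        self._x = x
        y = x @ self.w.value.T
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, gy):
        self.w.grad += gy.T @ self._x
        if self.b is not None:
            self.b.grad += gy.sum(axis=0)
        return gy @ self.w.value


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(p.dtype).tiny
    loss = float(-np.log(p[np.arange(n), y] + eps).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad ** 2 - v)
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
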