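"""Trainable layers with cached forward state and explicit backward passes."""

from __future__ import annotations

import numpy as np
from scipy.special import erf

from .ops import conv2d, conv2d_backward

_INV_SQRT2 = 1.0 / np.sqrt(2.0).astype(np.float32)
_INV_SQRT2PI = np.float32(1.0 / np.sqrt(2.0 * np.pi))


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Minimal module base: parameter collection over attributes."""

    def params(self) -> list[Param]:
        out: list[Param] = []

        def collect(v) -> None:
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    collect(item)

        for v in vars(self).values():
            collect(v)
        return out

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(
        self,
        cin: int,
        cout: int,
        k: int,
        rng: np.random.Generator,
        stride: int = 1,
        bias: bool = True,
        name: str = "conv",
    ):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.stride = stride
        self.w = Param(_he_init(rng, (cout, cin, k, k), cin * k * k), f"{name}.w")
        self.b = Param(np.zeros(cout, dtype=np.float32), f"{name}.b") if bias else None
        self._x: np.ndarray | None = None
        self._cache: dict = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._cache = {}
        return conv2d(
            x, self.w.value, self.b.value if self.b else None, self.stride, self._cache
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx, dw, db = conv2d_backward(
            self._x, self.w.value, dy, self.stride, self._cache
        )
        self.w.grad += dw
        if self.b is not None:
            self.b.grad += db
        return dx


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "fc"):
        self.w = Param(_he_init(rng, (cin, cout), cin), f"{name}.w")
        self.b = Param(np.zeros(cout, dtype=np.float32), f"{name}.b")
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class GroupNorm(Module):
    """Group normalization over (C/G·H·W) groups with affine scale/shift."""

    def __init__(self, channels: int, groups: int, name: str = "gn", eps: float = 1e-5):
        if channels % groups != 0:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.groups = groups
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=np.float32), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), f"{name}.beta")
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        G = self.groups
        xg = x.reshape(B, G, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * inv).reshape(B, C, H, W).astype(np.float32)
        self._cache = (xhat, inv.astype(np.float32), (B, C, H, W))
        return xhat * self.gamma.value[None, :, None, None] + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, (B, C, H, W) = self._cache
        G = self.groups
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = (dy * self.gamma.value[None, :, None, None]).reshape(B, G, -1)
        xh = xhat.reshape(B, G, -1)
        m1 = dxhat.mean(axis=2, keepdims=True)
        m2 = (dxhat * xh).mean(axis=2, keepdims=True)
        dx = inv * (dxhat - m1 - xh * m2)
        return dx.reshape(B, C, H, W).astype(np.float32)


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact (erf-based) GELU."""
    return (0.5 * x * (1.0 + erf(x * _INV_SQRT2))).astype(np.float32)


def gelu_backward(x: np.ndarray, dy: np.ndarray) -> np.ndarray:
    cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2))
    pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
    return (dy * (cdf + x * pdf)).astype(np.float32)


def gelu_with_deriv(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(gelu(x), gelu'(x)) computed in one pass, for backward reuse."""
    cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2))
    pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
    return (x * cdf).astype(np.float32), (cdf + x * pdf).astype(np.float32)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float32)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)
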