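"""Minimal numpy neural-network layers with hand-written backward passes.

Everything the dilated-convolutional masked LM needs: embedding lookup,
linear maps, layer normalization, GELU, dilated 1-D convolution with
same-length zero padding, and Adam. Layers cache forward activations and
consume them in a single backward call (one forward per backward, as used
by the training loop). All activations are float32; shapes are (B, L, C).

Gradient correctness is pinned by finite-difference tests rather than an
autograd engine.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy.special import erf

_SQRT2 = np.float32(np.sqrt(2.0))
_INV_SQRT_2PI = np.float32(1.0 / np.sqrt(2.0 * np.pi))


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    cdf = 0.5 * (1.0 + erf(x / _SQRT2))
    pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    return cdf + x * pdf


class Module:
    def params(self) -> list[Param]:
        raise NotImplementedError


class Linear(Module):
    """Position-wise affine map (B, L, Cin) -> (B, L, Cout)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, name: str = "") -> None:
        std = np.sqrt(2.0 / (c_in + c_out))
        self.W = Param(rng.normal(0.0, std, size=(c_in, c_out)), name + ".W")
        self.b = Param(np.zeros(c_out), name + ".b")
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self.W.grad += np.tensordot(x, dy, axes=([0, 1], [0, 1]))
        self.b.grad += dy.sum(axis=(0, 1))
        return dy @ self.W.value.T

    def params(self) -> list[Param]:
        return [self.W, self.b]


class LayerNorm(Module):
    """Normalization over the channel (last) axis with learned scale/shift."""

    def __init__(self, dim: int, name: str = "", eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(dim), name + ".gamma")
        self.beta = Param(np.zeros(dim), name + ".beta")
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1))
        self.beta.grad += dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma.value
        d = xhat.shape[-1]
        return (dxhat - dxhat.mean(axis=-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)) * inv

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class GELU(Module):
    def __init__(self) -> None:
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return gelu(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * gelu_grad(self._x)

    def params(self) -> list[Param]:
        return []


class DilatedConv1d(Module):
    """Kernel-``k`` dilated convolution along L with same-length zero padding.

    y[t] = b + sum_j x[t + (j - k//2) * dilation] @ W[j], out-of-range taps zero.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 rng: np.random.Generator, name: str = "") -> None:
        if kernel % 2 != 1:
            raise ValueError("kernel width must be odd for same-length padding")
        std = np.sqrt(2.0 / (kernel * c_in + c_out))
        self.W = Param(rng.normal(0.0, std, size=(kernel, c_in, c_out)), name + ".W")
        self.b = Param(np.zeros(c_out), name + ".b")
        self.kernel = kernel
        self.dilation = dilation
        self._x: np.ndarray | None = None

    def _shift(self, x: np.ndarray, offset: int) -> np.ndarray:
        """x shifted so out[t] = x[t + offset], zero-padded."""
        if offset == 0:
            return x
        out = np.zeros_like(x)
        if offset > 0:
            out[:, :-offset] = x[:, offset:]
        else:
            out[:, -offset:] = x[:, :offset]
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        half = self.kernel // 2
        y = np.broadcast_to(self.b.value, x.shape[:2] + (self.W.value.shape[2],)).copy()
        for j in range(self.kernel):
            off = (j - half) * self.dilation
            y += self._shift(x, off) @ self.W.value[j]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        half = self.kernel // 2
        dx = np.zeros_like(x)
        self.b.grad += dy.sum(axis=(0, 1))
        for j in range(self.kernel):
            off = (j - half) * self.dilation
            xs = self._shift(x, off)
            self.W.grad[j] += np.tensordot(xs, dy, axes=([0, 1], [0, 1]))
            dx += self._shift(dy @ self.W.value[j].T, -off)
        return dx

    def params(self) -> list[Param]:
        return [self.W, self.b]


class Adam:
    """Adam with per-parameter first/second moment state."""

    def __init__(self, params: Iterable[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad.fill(0.0)

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
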