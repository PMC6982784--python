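"""Minimal CPU neural-network layers with explicit reverse-mode gradients.

Everything operates on single images as ``(C, H, W)`` float64 arrays (one
image per optimization, so there is no batch axis). Each layer caches what
its ``backward`` needs during ``forward``; ``backward`` consumes the
gradient of the loss w.r.t. the layer output and returns the gradient
w.r.t. the input, accumulating parameter gradients in ``.grads``.

Convolutions use reflection padding (to avoid border artifacts) and are
evaluated as im2col + BLAS matmul, which is the fastest pure-numpy route
at the feature-map sizes used here.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "LeakyReLU",
    "BilinearUp2",
    "Sequential",
    "Adam",
]


class Layer:
    """Base: parameter-free unless overridden."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _reflect_pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (p, p), (p, p)), mode="reflect")


def _fold_axis(d: np.ndarray, p: int, axis: int) -> np.ndarray:
    """Adjoint of reflect-padding along one axis: fold pad gradients inward.

    np.pad 'reflect' sets padded[j] = x[p-j] on the left and
    padded[p+n+j] = x[n-2-j] on the right; the adjoint accumulates those
    entries back onto their sources.
    """
    d = np.moveaxis(d, axis, 0)
    n = d.shape[0] - 2 * p
    core = d[p : p + n].copy()
    core[1 : p + 1] += d[:p][::-1]
    core[n - 1 - p : n - 1] += d[p + n :][::-1]
    return np.moveaxis(core, 0, axis)


def _reflect_pad_adjoint(dpad: np.ndarray, p: int) -> np.ndarray:
    """Adjoint of reflection padding on both spatial axes."""
    if p == 0:
        return dpad
    return _fold_axis(_fold_axis(dpad, p, 1), p, 2)


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with reflection padding.

    Weight shape ``(C_out, C_in, k, k)``; odd ``k`` only, "same" spatial
    size divided by ``stride``.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        slope: float = 0.1,
    ) -> None:
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {kernel}")
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        gain = np.sqrt(2.0 / (1.0 + slope**2))  # He init for leaky-ReLU nets
        self.w = rng.normal(0.0, gain / np.sqrt(fan_in), (c_out, c_in, kernel, kernel))
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        assert c == self.c_in, f"expected {self.c_in} channels, got {c}"
        p, s, k = self.k // 2, self.stride, self.k
        xp = _reflect_pad(x, p)
        ho, wo = h // s, w // s
        sc, sh, sw = xp.strides
        windows = np.lib.stride_tricks.as_strided(
            xp,
            shape=(c, k, k, ho, wo),
            strides=(sc, sh, sw, sh * s, sw * s),
            writeable=False,
        )
        cols = windows.reshape(c * k * k, ho * wo)
        out = self.w.reshape(self.c_out, -1) @ cols + self.b[:, None]
        self._cols = np.ascontiguousarray(cols)
        self._xshape = x.shape
        return out.reshape(self.c_out, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, h, w = self._xshape
        p, s, k = self.k // 2, self.stride, self.k
        ho, wo = h // s, w // s
        dflat = dout.reshape(self.c_out, -1)
        self.grads[0] += (dflat @ self._cols.T).reshape(self.w.shape)
        self.grads[1] += dflat.sum(axis=1)
        dcols = (self.w.reshape(self.c_out, -1).T @ dflat).reshape(c, k, k, ho, wo)
        dxp = np.zeros((c, h + 2 * p, w + 2 * p))
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki : ki + s * ho : s, kj : kj + s * wo : s] += dcols[:, ki, kj]
        return _reflect_pad_adjoint(dxp, p)


class BatchNorm2d(Layer):
    """Per-channel normalization over the spatial axes (single-image batch)."""

    eps = 1e-5

    def __init__(self, c: int) -> None:
        super().__init__()
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        return self.gamma[:, None, None] * self._xhat + self.beta[:, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        m = dout.shape[1] * dout.shape[2]
        self.grads[0] += (dout * self._xhat).sum(axis=(1, 2))
        self.grads[1] += dout.sum(axis=(1, 2))
        dxhat = dout * self.gamma[:, None, None]
        return (
            self._istd
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(1, 2), keepdims=True)
                - self._xhat * (dxhat * self._xhat).sum(axis=(1, 2), keepdims=True)
            )
        )


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._neg, self.slope * dout, dout)


class BilinearUp2(Layer):
    """×2 bilinear upsampling as two one-axis interpolation matmuls.

    The interpolation matrix A (2n × n) is dense but tiny at these sizes;
    the backward pass is its exact transpose, so the layer is a linear
    operator with an exact adjoint.
    """

    _cache: dict[int, np.ndarray] = {}

    @classmethod
    def _matrix(cls, n: int) -> np.ndarray:
        a = cls._cache.get(n)
        if a is None:
            a = np.zeros((2 * n, n))
            src = np.clip((np.arange(2 * n) + 0.5) / 2.0 - 0.5, 0, n - 1)
            i0 = np.floor(src).astype(int)
            i1 = np.minimum(i0 + 1, n - 1)
            frac = src - i0
            a[np.arange(2 * n), i0] += 1.0 - frac
            a[np.arange(2 * n), i1] += frac
            cls._cache[n] = a
        return a

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = self._matrix(x.shape[1])
        self._n = x.shape[1]
        return np.matmul(np.matmul(a, x), a.T)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        a = self._matrix(self._n)
        return np.matmul(np.matmul(a.T, dout), a)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    @property
    def params(self) -> list[np.ndarray]:  # type: ignore[override]
        return [p for lay in self.layers for p in lay.params]

    @params.setter
    def params(self, value) -> None:  # Layer.__init__ compatibility
        pass

    @property
    def grads(self) -> list[np.ndarray]:  # type: ignore[override]
        return [g for lay in self.layers for g in lay.grads]

    @grads.setter
    def grads(self, value) -> None:
        pass

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place updates)."""

    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float = 0.01,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0
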