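"""Minimal CPU neural-network layers with explicit backward passes.

Everything operates on float32 arrays shaped ``(batch, channels, height,
width)`` (or ``(batch, features)`` for linear layers).  Each layer caches
what its backward pass needs during ``forward`` and accumulates parameter
gradients into ``Parameter.grad`` during ``backward``.  Weight
initialization is driven by an explicit ``numpy.random.Generator`` so that
two networks built from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Parameter:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: subclasses implement forward/backward and list parameters."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    __call__ = lambda self, x: self.forward(x)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Layer):
    """2-D convolution, stride 1, odd kernel, 'same' zero padding.

    Implemented as im2col + one matmul; the col2im in ``backward`` loops over
    the k*k kernel offsets only, so it stays vectorized over batch and space.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, name: str = "conv"):
        if k % 2 != 1:
            raise ValueError("Conv2d requires an odd kernel size")
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2
        fan_in = cin * k * k
        self.W = Parameter(_he_init(rng, (cout, fan_in), fan_in), f"{name}.W")
        self.b = Parameter(np.zeros(cout), f"{name}.b")
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def _im2col(self, xp: np.ndarray, H: int, Wd: int) -> np.ndarray:
        B = xp.shape[0]
        k = self.k
        cols = np.empty((B, self.cin, k * k, H * Wd), dtype=DTYPE)
        for ki in range(k):
            for kj in range(k):
                cols[:, :, ki * k + kj, :] = xp[:, :, ki:ki + H, kj:kj + Wd].reshape(B, self.cin, -1)
        return cols.reshape(B, self.cin * k * k, H * Wd)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, Wd = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = self._im2col(xp, H, Wd)
        y = self.W.data @ cols  # (B, cout, H*W) via broadcasting
        y += self.b.data[None, :, None]
        self._cache = (cols, (B, C, H, Wd))
        return np.ascontiguousarray(y.reshape(B, self.cout, H, Wd))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, (B, C, H, Wd) = self._cache
        k, p = self.k, self.pad
        gym = gy.reshape(B, self.cout, H * Wd)
        self.W.grad += np.einsum("bop,bfp->of", gym, cols, optimize=True)
        self.b.grad += gym.sum(axis=(0, 2))
        gcols = (self.W.data.T @ gym).reshape(B, C, k * k, H, Wd)
        gxp = np.zeros((B, C, H + 2 * p, Wd + 2 * p), dtype=DTYPE)
        for ki in range(k):
            for kj in range(k):
                gxp[:, :, ki:ki + H, kj:kj + Wd] += gcols[:, :, ki * k + kj]
        return gxp[:, :, p:p + H, p:p + Wd]


class ConvTranspose2d(Layer):
    """2x2 transpose convolution with stride 2 (learned 2x upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "up"):
        self.cin, self.cout = cin, cout
        self.W = Parameter(_he_init(rng, (cin, cout, 2, 2), cin), f"{name}.W")
        self.b = Parameter(np.zeros(cout), f"{name}.b")
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, Wd = x.shape
        tmp = np.einsum("bchw,codk->bohwdk", x, self.W.data, optimize=True)
        y = tmp.transpose(0, 1, 2, 4, 3, 5).reshape(B, self.cout, 2 * H, 2 * Wd)
        y += self.b.data[None, :, None, None]
        self._x = x
        return np.ascontiguousarray(y)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        B, C, H, Wd = x.shape
        gtmp = gy.reshape(B, self.cout, H, 2, Wd, 2).transpose(0, 1, 2, 4, 3, 5)
        self.W.grad += np.einsum("bchw,bohwdk->codk", x, gtmp, optimize=True)
        self.b.grad += gy.sum(axis=(0, 2, 3))
        return np.einsum("bohwdk,codk->bchw", gtmp, self.W.data, optimize=True)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2."""

    def __init__(self):
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, Wd = x.shape
        xr = x.reshape(B, C, H // 2, 2, Wd // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = np.ascontiguousarray(xr).reshape(B, C, H // 2, Wd // 2, 4)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (B, C, H, Wd))
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        idx, (B, C, H, Wd) = self._cache
        gflat = np.zeros((B, C, H // 2, Wd // 2, 4), dtype=DTYPE)
        np.put_along_axis(gflat, idx[..., None], gy[..., None], axis=-1)
        gx = gflat.reshape(B, C, H // 2, Wd // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(gx).reshape(B, C, H, Wd)


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0.0).astype(DTYPE, copy=False)


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "fc"):
        self.W = Parameter(_he_init(rng, (cout, cin), cin), f"{name}.W")
        self.b = Parameter(np.zeros(cout), f"{name}.b")
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.data.T + self.b.data

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.W.grad += gy.T @ self._x
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.data


class ConvBlock(Layer):
    """Two same-padded 3x3 convolutions, each followed by ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "block"):
        self.layers = [
            Conv2d(cin, cout, 3, rng, f"{name}.c1"),
            ReLU(),
            Conv2d(cout, cout, 3, rng, f"{name}.c2"),
            ReLU(),
        ]

    def parameters(self) -> list[Parameter]:
        return [p for lyr in self.layers for p in lyr.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lyr in self.layers:
            x = lyr.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for lyr in reversed(self.layers):
            gy = lyr.backward(gy)
        return gy


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
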