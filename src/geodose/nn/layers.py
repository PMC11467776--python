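"""Layer primitives with explicit forward caches and backward passes.

Tensors are (N, C, D, H, W) float64 arrays; D is the superior-inferior (z)
axis. Convolutions use same-padding so spatial dims are preserved within a
level; all down/up-sampling is by a factor of 2 per axis.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    """Base: layers own parameters and a cache from the latest forward."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """Same-padded 3D convolution (offset-sum formulation: one BLAS matmul
    per kernel tap, no im2col buffer)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 name: str = "conv", dtype=np.float64):
        k = kernel
        fan_in = c_in * k**3
        self.w = Param(
            rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(c_out, c_in, k, k, k)).astype(dtype),
            f"{name}.w",
        )
        self.b = Param(np.zeros(c_out, dtype=dtype), f"{name}.b")
        self.k = k

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        k, p = self.k, self.k // 2
        n, ci, d, h, w = x.shape
        self._x_padded = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        co = self.w.value.shape[0]
        y = np.empty((n, co, d, h, w), dtype=self.w.value.dtype)
        y[:] = self.b.value[None, :, None, None, None]
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = self._x_padded[:, :, i : i + d, j : j + h, l : l + w]
                    y += np.tensordot(
                        self.w.value[:, :, i, j, l], xs, axes=([1], [1])
                    ).transpose(1, 0, 2, 3, 4)
        self._in_shape = x.shape
        return y

    def backward(self, dy):
        k, p = self.k, self.k // 2
        n, ci, d, h, w = self._in_shape
        dxp = np.zeros_like(self._x_padded)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = self._x_padded[:, :, i : i + d, j : j + h, l : l + w]
                    self.w.grad[:, :, i, j, l] += np.tensordot(
                        dy, xs, axes=([0, 2, 3, 4], [0, 2, 3, 4])
                    )
                    dxp[:, :, i : i + d, j : j + h, l : l + w] += np.tensordot(
                        self.w.value[:, :, i, j, l], dy, axes=([0], [1])
                    ).transpose(1, 0, 2, 3, 4)
        self.b.grad += dy.sum(axis=(0, 2, 3, 4))
        if p == 0:
            return dxp
        return dxp[:, :, p:-p, p:-p, p:-p]


class CReLU(Layer):
    """Concatenated rectification: cat(relu(x), relu(-x)) doubles channels,
    preserving both signs of the pre-activation."""

    def forward(self, x, training=False):
        self._pos = x > 0
        return np.concatenate([np.where(self._pos, x, 0.0),
                               np.where(self._pos, 0.0, -x)], axis=1)

    def backward(self, dy):
        c = dy.shape[1] // 2
        return np.where(self._pos, dy[:, :c], -dy[:, c:])


class GroupNorm(Layer):
    def __init__(self, channels: int, groups: int, name: str = "gn", eps: float = 1e-5,
                 dtype=np.float64):
        if channels % groups != 0:
            raise ValueError(f"{groups} groups do not divide {channels} channels")
        self.groups = groups
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=dtype), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), f"{name}.beta")

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        n, c = x.shape[:2]
        g = self.groups
        xg = x.reshape(n, g, -1)
        mean = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = ((xg - mean) * self._inv_std).reshape(x.shape)
        return self.gamma.value[None, :, None, None, None] * self._xhat + \
            self.beta.value[None, :, None, None, None]

    def backward(self, dy):
        n, c = dy.shape[:2]
        g = self.groups
        self.gamma.grad += (dy * self._xhat).sum(axis=(0, 2, 3, 4))
        self.beta.grad += dy.sum(axis=(0, 2, 3, 4))
        dxhat = (dy * self.gamma.value[None, :, None, None, None]).reshape(n, g, -1)
        xhat = self._xhat.reshape(n, g, -1)
        m = dxhat.shape[2]
        dx = (
            dxhat
            - dxhat.mean(axis=2, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=2, keepdims=True)
        ) * self._inv_std
        return dx.reshape(dy.shape)


class DualPool(Layer):
    """Downsampling: concatenation of 2x2x2 max-pool and average-pool
    (doubles channels, halves each spatial dim)."""

    def forward(self, x, training=False):
        n, c, d, h, w = x.shape
        xb = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        xb = xb.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, d // 2, h // 2, w // 2, 8
        )
        self._argmax = xb.argmax(axis=-1)
        self._in_shape = x.shape
        return np.concatenate([xb.max(axis=-1), xb.mean(axis=-1)], axis=1)

    def backward(self, dy):
        n, c, d, h, w = self._in_shape
        dmax, davg = dy[:, : c], dy[:, c:]
        db = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=dy.dtype)
        np.put_along_axis(db, self._argmax[..., None], dmax[..., None], axis=-1)
        db += davg[..., None] / 8.0
        db = db.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
        return db.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)


def _interp_matrix(out_len: int, in_len: int, mode: str) -> np.ndarray:
    """Per-axis factor-2 upsampling operator (out_len = 2 * in_len)."""
    a = np.zeros((out_len, in_len))
    for o in range(out_len):
        pos = (o + 0.5) / 2.0 - 0.5
        if mode == "nearest":
            a[o, int(np.clip(round(pos), 0, in_len - 1))] = 1.0
        else:  # linear with edge clamp
            lo = int(np.floor(pos))
            frac = pos - lo
            lo_c = int(np.clip(lo, 0, in_len - 1))
            hi_c = int(np.clip(lo + 1, 0, in_len - 1))
            a[o, lo_c] += 1.0 - frac
            a[o, hi_c] += frac
    return a


class DualUpsample(Layer):
    """Upsampling: concatenation of nearest-neighbour and trilinear factor-2
    interpolation (doubles channels, doubles each spatial dim)."""

    def __init__(self):
        self._mats: dict[tuple[int, str], np.ndarray] = {}

    def _mat(self, in_len: int, mode: str) -> np.ndarray:
        key = (in_len, mode)
        if key not in self._mats:
            self._mats[key] = _interp_matrix(2 * in_len, in_len, mode)
        return self._mats[key]

    def _apply(self, x, mode: str, transpose: bool) -> np.ndarray:
        y = x
        for axis in (2, 3, 4):
            n_in = y.shape[axis]
            a = self._mat(n_in // 2 if transpose else n_in, mode)
            a = a.astype(y.dtype, copy=False)
            if transpose:
                a = a.T
            y = np.moveaxis(np.tensordot(y, a, axes=([axis], [1])), -1, axis)
        return y

    def forward(self, x, training=False):
        self._in_channels = x.shape[1]
        return np.concatenate(
            [self._apply(x, "nearest", False), self._apply(x, "linear", False)],
            axis=1,
        )

    def backward(self, dy):
        c = self._in_channels
        return self._apply(dy[:, :c], "nearest", True) + self._apply(
            dy[:, c:], "linear", True
        )


class DropBlock3d(Layer):
    """Structured dropout: contiguous spatial blocks are zeroed in training.

    The block edge is drawn uniformly from 1..max_size per call ("maximal
    block size" semantics); the seed-point rate is adjusted so the expected
    dropped fraction matches ``rate``. Masks are shared across channels.
    Identity in eval mode.
    """

    def __init__(self, rate: float, max_size: int, rng: np.random.Generator):
        self.rate = rate
        self.max_size = max_size
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        n, c, d, h, w = x.shape
        bs = int(self.rng.integers(1, self.max_size + 1))
        bs = min(bs, d, h, w)
        gamma = self.rate / bs**3
        seeds = self.rng.random((n, 1, d, h, w)) < gamma
        dropped = ndimage.maximum_filter(
            seeds.astype(np.uint8), size=(1, 1, bs, bs, bs), mode="constant"
        )
        keep = (1.0 - dropped).astype(x.dtype)
        denom = keep.mean(axis=(2, 3, 4), keepdims=True)
        denom = np.where(denom > 0, denom, 1.0)
        self._mask = keep / denom
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Concat(Layer):
    """Channel concatenation of two inputs (skip joins)."""

    def forward_pair(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        self._ca = a.shape[1]
        return np.concatenate([a, b], axis=1)

    def backward(self, dy):
        return dy[:, : self._ca], dy[:, self._ca :]
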