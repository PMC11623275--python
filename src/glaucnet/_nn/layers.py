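"""Minimal dimension-generic neural-network layers on numpy.

Forward/backward passes are written by hand; convolutions are lowered to a
single GEMM per layer via an im2col transform built from k^d strided-slice
copies, keeping the arithmetic inside BLAS. Tensors are channel-last,
``(N, *spatial, C)``, in float32 — this layout makes the im2col matrix and
every GEMM result contiguous without transposition. Layers cache what
their backward pass needs; ``backward`` must follow a ``forward`` with
``training=True``.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg.blas import dgemm as _dgemm
from scipy.linalg.blas import sgemm as _sgemm

from . import kernels

F32 = np.float32


def _gemm_acc(c: np.ndarray, a: np.ndarray, b: np.ndarray) -> None:
    """c += a @ b.T in place, all arguments C-contiguous 2-D of one dtype.

    Implemented as c.T = b @ a.T + c.T on the F-contiguous transposed
    views, so BLAS writes straight into ``c`` without temporaries.
    """
    gemm = _sgemm if c.dtype == np.float32 else _dgemm
    gemm(1.0, b.T, a.T, beta=1.0, c=c.T, trans_a=1, trans_b=0, overwrite_c=1)


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _out_side(side: int, k: int, stride: int, pad: int) -> int:
    return (side + 2 * pad - k) // stride + 1


class Conv(Layer):
    """d-dimensional convolution with kernel side ``k`` in every spatial
    dimension; weight stored as (out_channels, k^d * in_channels)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        k: int,
        ndim: int = 2,
        stride: int = 1,
        pad: int = 0,
        bias: bool = False,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ) -> None:
        self.cin, self.cout, self.k, self.ndim = in_channels, out_channels, k, ndim
        self.stride, self.pad, self.use_bias = stride, pad, bias
        fan_in = in_channels * k**ndim
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_channels), f"{name}.bias") if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _im2col(self, x: np.ndarray):
        """Return (cols, out_spatial); cols is (N*prod(out), k^d*cin)."""
        n = x.shape[0]
        spatial = x.shape[1:-1]
        if self.k == 1 and self.stride == 1 and self.pad == 0:
            return x.reshape(-1, self.cin), spatial
        if self.pad:
            pads = [(0, 0)] + [(self.pad, self.pad)] * self.ndim + [(0, 0)]
            x = np.pad(x, pads)
        out = tuple(_out_side(s, self.k, self.stride, self.pad) for s in spatial)
        cols = np.empty((n,) + out + (self.k**self.ndim, self.cin), dtype=F32)
        for idx, off in enumerate(itertools.product(range(self.k), repeat=self.ndim)):
            sl = tuple(
                slice(o, o + out_s * self.stride, self.stride)
                for o, out_s in zip(off, out)
            )
            cols[..., idx, :] = x[(slice(None),) + sl]
        return cols.reshape(-1, self.k**self.ndim * self.cin), out

    @property
    def _use_shift(self) -> bool:
        # 3x3 stride-1 pad-1 2-D convolutions skip im2col entirely: the
        # convolution is 9 GEMMs on contiguous shifted views of the padded
        # plane; shift-corrupted outputs land only in discarded pad cells.
        return self.k == 3 and self.stride == 1 and self.pad == 1 and self.ndim == 2

    def _forward_shift(self, x, training):
        n, h, w, c = x.shape
        hp, wp = h + 2, w + 2
        xp = np.zeros((n, hp, wp, c), dtype=F32)
        xp[:, 1:-1, 1:-1] = x
        xg = xp.reshape(-1, c)
        m = xg.shape[0]
        yg = np.zeros((m, self.cout), dtype=F32)
        wv = self.weight.value
        for idx in range(9):
            ki, kj = divmod(idx, 3)
            o = (ki - 1) * wp + (kj - 1)
            wk = np.ascontiguousarray(wv[:, idx * c:(idx + 1) * c])
            if o >= 0:
                _gemm_acc(yg[:m - o], xg[o:], wk)
            else:
                _gemm_acc(yg[-o:], xg[:m + o], wk)
        y = yg.reshape(n, hp, wp, self.cout)[:, 1:-1, 1:-1]
        if self.bias is not None:
            y += self.bias.value
        if training:
            self._cache = (xg, x.shape)
        return np.ascontiguousarray(y)

    def _backward_shift(self, dy):
        xg, x_shape = self._cache
        self._cache = None
        n, h, w, c = x_shape
        hp, wp = h + 2, w + 2
        dyp = np.zeros((n, hp, wp, self.cout), dtype=F32)
        dyp[:, 1:-1, 1:-1] = dy
        dyg = dyp.reshape(-1, self.cout)
        m = dyg.shape[0]
        dw = self.weight.grad
        wv = self.weight.value
        dxg = np.zeros((m, c), dtype=F32)
        for idx in range(9):
            ki, kj = divmod(idx, 3)
            o = (ki - 1) * wp + (kj - 1)
            wk = np.ascontiguousarray(wv[:, idx * c:(idx + 1) * c])
            if o >= 0:
                dw[:, idx * c:(idx + 1) * c] += dyg[:m - o].T @ xg[o:]
                _gemm_acc(dxg[o:], dyg[:m - o], np.ascontiguousarray(wk.T))
            else:
                dw[:, idx * c:(idx + 1) * c] += dyg[-o:].T @ xg[:m + o]
                _gemm_acc(dxg[:m + o], dyg[-o:], np.ascontiguousarray(wk.T))
        if self.bias is not None:
            self.bias.grad += dyg.sum(axis=0)
        return np.ascontiguousarray(dxg.reshape(n, hp, wp, c)[:, 1:-1, 1:-1])

    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=F32)
        if self._use_shift:
            return self._forward_shift(x, training)
        cols, out = self._im2col(x)
        y = cols @ self.weight.value.T
        if self.bias is not None:
            y += self.bias.value
        if training:
            self._cache = (cols, x.shape, out)
        return y.reshape((x.shape[0],) + out + (self.cout,))

    def backward(self, dy):
        if self._use_shift:
            return self._backward_shift(dy)
        cols, x_shape, out = self._cache
        n = x_shape[0]
        dy_m = dy.reshape(-1, self.cout)
        self.weight.grad += dy_m.T @ cols
        if self.bias is not None:
            self.bias.grad += dy_m.sum(axis=0)
        dcols = dy_m @ self.weight.value  # (N*prod(out), k^d*cin)
        self._cache = None
        if self.k == 1 and self.stride == 1 and self.pad == 0:
            return dcols.reshape(x_shape)
        dcols = dcols.reshape((n,) + out + (self.k**self.ndim, self.cin))
        padded = tuple(s + 2 * self.pad for s in x_shape[1:-1])
        dxp = np.zeros((n,) + padded + (self.cin,), dtype=F32)
        for idx, off in enumerate(itertools.product(range(self.k), repeat=self.ndim)):
            sl = tuple(
                slice(o, o + out_s * self.stride, self.stride)
                for o, out_s in zip(off, out)
            )
            dxp[(slice(None),) + sl] += dcols[..., idx, :]
        if self.pad:
            core = tuple(slice(self.pad, p - self.pad) for p in padded)
            dxp = dxp[(slice(None),) + core]
        return np.ascontiguousarray(dxp)


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics.

    ``relu=True`` fuses a ReLU into the layer (one pass instead of three);
    the normalized pre-activation is never materialized — the backward
    reductions are folded into per-channel constants algebraically.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 relu: bool = False, name: str = "bn") -> None:
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self.relu = relu
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        c = x.shape[-1]
        flat = np.ascontiguousarray(x.reshape(-1, c))
        if training:
            m = flat.shape[0]
            s, q = kernels.col_mean_sq(flat)
            mean = s / m
            var = np.maximum(q / m - mean * mean, 0.0)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(flat.dtype)
        mean = mean.astype(flat.dtype)
        scale = self.gamma.value * invstd
        shift = self.beta.value - mean * scale
        if self.relu:
            y = kernels.affine_relu(flat, scale, shift)
        else:
            y = flat * scale
            y += shift
        if training:
            self._cache = (flat, mean, invstd, scale, shift, x.shape)
        return y.reshape(x.shape)

    def backward(self, dy):
        """Note: consumes ``dy`` (modified in place when contiguous)."""
        flat, mean, invstd, scale, shift, shape = self._cache
        self._cache = None
        c = shape[-1]
        dflat = dy.reshape(-1, c)
        if dflat.dtype != flat.dtype or not dflat.flags.writeable \
                or not dflat.flags.c_contiguous:
            dflat = np.ascontiguousarray(dflat, dtype=flat.dtype)
        m = dflat.shape[0]
        if self.relu:
            db, df = kernels.bn_relu_backward_reduce(dflat, flat, scale, shift)
        else:
            db = dflat.sum(axis=0, dtype=np.float64)
            df = np.einsum("ij,ij->j", dflat.astype(np.float64),
                           flat.astype(np.float64))
        db = db.astype(flat.dtype)
        # sum(dy * xhat) = (sum(dy*x) - mean*sum(dy)) * invstd
        dg = (df.astype(flat.dtype) - mean * db) * invstd
        self.gamma.grad += dg
        self.beta.grad += db
        # dx = scale*dy + B*x + C  (per-channel constants)
        b_coef = -scale * invstd * dg / m
        c_coef = scale * (dg * invstd * mean - db) / m
        kernels.bn_backward_dx(dflat, flat, scale, b_coef.astype(flat.dtype),
                               c_coef.astype(flat.dtype))
        return dflat.reshape(shape)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training=False):
        y = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class NearestUpsample(Layer):
    """Doubles every spatial side by nearest-neighbour repetition."""

    def forward(self, x, training=False):
        y = x
        for ax in range(1, x.ndim - 1):
            y = np.repeat(y, 2, axis=ax)
        return y

    def backward(self, dy):
        for ax in range(1, dy.ndim - 1):
            n = dy.shape[ax]
            shape = dy.shape[:ax] + (n // 2, 2) + dy.shape[ax + 1:]
            dy = dy.reshape(shape).sum(axis=ax + 1)
        return np.ascontiguousarray(dy)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng=None, name: str = "fc"):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(n_out), f"{name}.bias")
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, training=False):
        if training:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy):
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        dx = dy @ self.weight.value
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout: scales kept units by 1/(1-p) at train time so that
    evaluation is the deterministic identity (expectation-equivalent to
    keeping all units and halving their outputs at test time for p=0.5)."""

    def __init__(self, p: float):
        if not (0 <= p < 1):
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self._mask = None

    def forward(self, x, training=False, rng: np.random.Generator | None = None):
        if not training or self.p == 0:
            return x
        if rng is None:
            raise ValueError("Dropout requires an rng during training")
        mask = (rng.random(x.shape) >= self.p).astype(F32) / F32(1.0 - self.p)
        self._mask = mask
        return x * mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


def global_average_pool(x: np.ndarray) -> np.ndarray:
    """(N, *spatial, C) -> (N, C) mean over all spatial axes."""
    return x.reshape(x.shape[0], -1, x.shape[-1]).mean(axis=1)


def global_average_pool_backward(dy: np.ndarray, spatial: tuple) -> np.ndarray:
    npix = int(np.prod(spatial))
    g = (dy / npix).astype(F32)
    shape = (g.shape[0],) + spatial + (g.shape[1],)
    return np.broadcast_to(
        g.reshape((g.shape[0],) + (1,) * len(spatial) + (g.shape[1],)), shape
    ).copy()


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
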