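"""Numba-fused kernels for the batch-normalization hot path.

BatchNorm touches every activation several times per step; fusing the
per-column reductions and the affine+ReLU application into single passes
roughly halves its memory traffic. Reductions accumulate in float64 for
stability. All kernels are deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def col_mean_sq(flat):
    """Per-column sum and sum of squares of a (m, c) array, in float64."""
    m, c = flat.shape
    s = np.zeros(c, dtype=np.float64)
    q = np.zeros(c, dtype=np.float64)
    for i in range(m):
        for j in range(c):
            v = np.float64(flat[i, j])
            s[j] += v
            q[j] += v * v
    return s, q


@njit(cache=True, fastmath=True)
def affine_relu(flat, scale, shift):
    """max(flat * scale + shift, 0) columnwise, one pass."""
    m, c = flat.shape
    out = np.empty_like(flat)
    for i in range(m):
        for j in range(c):
            v = flat[i, j] * scale[j] + shift[j]
            out[i, j] = v if v > 0 else 0
    return out


@njit(cache=True, fastmath=True)
def bn_relu_backward_reduce(dy, flat, scale, shift):
    """Mask ``dy`` in place by the ReLU derivative (recomputed from the
    pre-activation) and return per-column sums of dy and dy*flat."""
    m, c = dy.shape
    db = np.zeros(c, dtype=np.float64)
    df = np.zeros(c, dtype=np.float64)
    for i in range(m):
        for j in range(c):
            pre = flat[i, j] * scale[j] + shift[j]
            if pre <= 0:
                dy[i, j] = 0
            else:
                g = np.float64(dy[i, j])
                db[j] += g
                df[j] += g * np.float64(flat[i, j])
    return db, df


@njit(cache=True, fastmath=True)
def bn_backward_dx(dy, flat, a, b, c0):
    """dy <- dy*a + flat*b + c0 columnwise, in place."""
    m, c = dy.shape
    for i in range(m):
        for j in range(c):
            dy[i, j] = dy[i, j] * a[j] + flat[i, j] * b[j] + c0[j]
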