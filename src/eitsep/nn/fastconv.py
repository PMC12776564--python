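"""Numba direct 3x3 convolution kernels (single-thread, float32).

For the small channel counts used here a direct convolution with explicit
loops over a zero-padded input beats im2col + GEMM by keeping each HxW
plane in L1 and avoiding the patch-matrix shuffle.  The pure-numpy im2col
path in :mod:`eitsep.nn.layers` remains the reference implementation; a
unit test pins both backends to identical outputs.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore[misc]
        if len(a) == 1 and callable(a[0]):
            return a[0]
        return lambda f: f


def pad_input(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1))).astype(np.float32)


@njit(cache=True, fastmath=True)
def conv3x3_forward(xp, w, b):  # pragma: no cover - jitted
    n, c_in, hp, wp = xp.shape
    h, wd = hp - 2, wp - 2
    c_out = w.shape[0]
    y = np.empty((n, c_out, h, wd), dtype=np.float32)
    acc = np.empty(wd, dtype=np.float32)
    for nn_ in range(n):
        for co in range(c_out):
            for i in range(h):
                for j in range(wd):
                    acc[j] = b[co]
                for ci in range(c_in):
                    for ki in range(3):
                        w0 = w[co, ci, ki, 0]
                        w1 = w[co, ci, ki, 1]
                        w2 = w[co, ci, ki, 2]
                        row = xp[nn_, ci, i + ki]
                        for j in range(wd):
                            acc[j] += (w0 * row[j] + w1 * row[j + 1]
                                       + w2 * row[j + 2])
                for j in range(wd):
                    y[nn_, co, i, j] = acc[j]
    return y


@njit(cache=True, fastmath=True)
def conv3x3_backward(xp, w, dy):  # pragma: no cover - jitted
    n, c_in, hp, wp = xp.shape
    h, wd = hp - 2, wp - 2
    c_out = w.shape[0]
    dxp = np.zeros((n, c_in, hp, wp), dtype=np.float32)
    dw = np.zeros_like(w)
    db = np.zeros(c_out, dtype=np.float32)
    for nn_ in range(n):
        for co in range(c_out):
            s = np.float32(0.0)
            for i in range(h):
                for j in range(wd):
                    s += dy[nn_, co, i, j]
            db[co] += s
            for ci in range(c_in):
                for ki in range(3):
                    for kj in range(3):
                        wv = w[co, ci, ki, kj]
                        s = np.float32(0.0)
                        for i in range(h):
                            for j in range(wd):
                                d = dy[nn_, co, i, j]
                                s += d * xp[nn_, ci, i + ki, j + kj]
                                dxp[nn_, ci, i + ki, j + kj] += wv * d
                        dw[co, ci, ki, kj] += s
    return dxp[:, :, 1:-1, 1:-1], dw, db
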