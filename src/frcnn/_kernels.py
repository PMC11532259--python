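"""Numba inner loops for the convolution and mixed-pooling layers.

The NHWC layouts here have few channels, where pure-numpy broadcasting
spends most of its time on temporaries; these fused serial loops keep
the layer contracts bit-identical (first-occurrence argmax ties,
float32 or float64 as passed in) while running near memory bandwidth.
Kernels are cached on first compilation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["conv2d_fwd", "conv2d_bwd", "mixed_pool_fwd", "mixed_pool_bwd"]


@njit(cache=True, fastmath=True)
def im2col(x, kh, kw):
    """Gather valid stride-1 patches into (n*ho*wo, kh*kw*ci), (u,v,c) order."""
    n, h, w, ci = x.shape
    ho, wo = h - kh + 1, w - kw + 1
    cols = np.empty((n * ho * wo, kh * kw * ci), dtype=x.dtype)
    for nn in range(n):
        for i in range(ho):
            for j in range(wo):
                row = (nn * ho + i) * wo + j
                p = 0
                for u in range(kh):
                    for v in range(kw):
                        for c in range(ci):
                            cols[row, p] = x[nn, i + u, j + v, c]
                            p += 1
    return cols


@njit(cache=True, fastmath=True)
def col2im_add(cols, n, h, w, ci, kh, kw):
    """Scatter-add patch-gradient rows back onto the input grid."""
    ho, wo = h - kh + 1, w - kw + 1
    dx = np.zeros((n, h, w, ci), dtype=cols.dtype)
    for nn in range(n):
        for i in range(ho):
            for j in range(wo):
                row = (nn * ho + i) * wo + j
                p = 0
                for u in range(kh):
                    for v in range(kw):
                        for c in range(ci):
                            dx[nn, i + u, j + v, c] += cols[row, p]
                            p += 1
    return dx


def conv2d_fwd(x, w):
    kh, kw, ci, co = w.shape
    n, h, wd, _ = x.shape
    ho, wo = h - kh + 1, wd - kw + 1
    cols = im2col(x, kh, kw)
    out = (cols @ w.reshape(kh * kw * ci, co)).reshape(n, ho, wo, co)
    return out, cols


def conv2d_bwd(cols, x_shape, w, dout, compute_dx):
    kh, kw, ci, co = w.shape
    n, h, wd, _ = x_shape
    dout_mat = dout.reshape(-1, co)
    dw = (cols.T @ dout_mat).reshape(w.shape)
    db = dout_mat.sum(axis=0)
    if not compute_dx:
        return None, dw, db
    dcols = dout_mat @ w.reshape(kh * kw * ci, co).T
    dx = col2im_add(dcols, n, h, wd, ci, kh, kw)
    return dx, dw, db


@njit(cache=True, fastmath=True)
def mixed_pool_fwd(x, ph, pw):
    n, h, w, c = x.shape
    ho, wo = h // ph, w // pw
    out = np.empty((n, ho, wo, 2 * c), dtype=x.dtype)
    idx = np.empty((n, ho, wo, c), dtype=np.int64)
    area = ph * pw
    for nn in range(n):
        for i in range(ho):
            for j in range(wo):
                for cc in range(c):
                    best = x[nn, i * ph, j * pw, cc]
                    bi = 0
                    s = x.dtype.type(0.0)
                    for u in range(ph):
                        for v in range(pw):
                            val = x[nn, i * ph + u, j * pw + v, cc]
                            s += val
                            if val > best:  # strict: first occurrence wins
                                best = val
                                bi = u * pw + v
                    out[nn, i, j, cc] = s / area
                    out[nn, i, j, c + cc] = best
                    idx[nn, i, j, cc] = bi
    return out, idx


@njit(cache=True, fastmath=True)
def mixed_pool_bwd(dout, idx, h, w, ph, pw):
    n, ho, wo, c2 = dout.shape
    c = c2 // 2
    dx = np.zeros((n, h, w, c), dtype=dout.dtype)
    area = dout.dtype.type(ph * pw)
    for nn in range(n):
        for i in range(ho):
            for j in range(wo):
                for cc in range(c):
                    g_avg = dout[nn, i, j, cc] / area
                    for u in range(ph):
                        for v in range(pw):
                            dx[nn, i * ph + u, j * pw + v, cc] += g_avg
                    bi = idx[nn, i, j, cc]
                    dx[nn, i * ph + bi // pw, j * pw + bi % pw, cc] += dout[
                        nn, i, j, c + cc
                    ]
    return dx
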