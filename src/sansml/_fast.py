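"""Numba kernels for the memory-bound pieces of the CNN stack.

The GEMMs already run on BLAS; what remains between them is pooling and the
im2col/col2im traffic, where explicit compiled loops beat numpy's strided
fancy indexing by a comfortable margin on a single core.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "maxpool2_fwd",
    "maxpool2_bwd",
    "col2im_add",
    "im2col",
    "bn_fwd_apply",
    "bn_bwd_apply",
]


@njit(cache=True, fastmath=True)
def _im2col(xpad, cols):
    # xpad: (n, H+2, W+2, c); cols: (n, H, W, 9, c)
    n, H, W, _, c = cols.shape
    for i in range(n):
        for r in range(H):
            for s in range(W):
                for k in range(9):
                    ki = k // 3
                    kj = k - 3 * ki
                    for ch in range(c):
                        cols[i, r, s, k, ch] = xpad[i, r + ki, s + kj, ch]


def im2col(xpad, cols):
    _im2col(xpad, cols)
    return cols


@njit(cache=True)
def bn_stats(x2, mu, var):
    # per-channel mean/variance in one pass, float64 accumulators
    n, c = x2.shape
    s = np.zeros(c, dtype=np.float64)
    ss = np.zeros(c, dtype=np.float64)
    for i in range(n):
        for ch in range(c):
            v = np.float64(x2[i, ch])
            s[ch] += v
            ss[ch] += v * v
    for ch in range(c):
        m = s[ch] / n
        mu[ch] = m
        var[ch] = max(ss[ch] / n - m * m, 0.0)


@njit(cache=True)
def bn_grads(dy2, xhat2, dgamma, dbeta):
    n, c = dy2.shape
    sg = np.zeros(c, dtype=np.float64)
    sb = np.zeros(c, dtype=np.float64)
    for i in range(n):
        for ch in range(c):
            d = np.float64(dy2[i, ch])
            sb[ch] += d
            sg[ch] += d * np.float64(xhat2[i, ch])
    for ch in range(c):
        dgamma[ch] = sg[ch]
        dbeta[ch] = sb[ch]


@njit(cache=True, fastmath=True)
def bn_fwd_apply(x2, mu, inv, gamma, beta, xhat2, y2):
    n, c = x2.shape
    for i in range(n):
        for ch in range(c):
            xh = (x2[i, ch] - mu[ch]) * inv[ch]
            xhat2[i, ch] = xh
            y2[i, ch] = xh * gamma[ch] + beta[ch]


@njit(cache=True, fastmath=True)
def bn_bwd_apply(dy2, xhat2, coef, ga, be, dx2):
    # dx = coef * (dy - be - xhat * ga), all per channel
    n, c = dy2.shape
    for i in range(n):
        for ch in range(c):
            dx2[i, ch] = coef[ch] * (dy2[i, ch] - be[ch] - xhat2[i, ch] * ga[ch])


@njit(cache=True, fastmath=True)
def _maxpool2_fwd(x, out, idx):
    n, H, W, c = x.shape
    h2, w2 = H // 2, W // 2
    for i in range(n):
        for r in range(h2):
            for s in range(w2):
                for ch in range(c):
                    best = x[i, 2 * r, 2 * s, ch]
                    bi = np.uint8(0)
                    v = x[i, 2 * r, 2 * s + 1, ch]
                    if v > best:
                        best = v
                        bi = np.uint8(1)
                    v = x[i, 2 * r + 1, 2 * s, ch]
                    if v > best:
                        best = v
                        bi = np.uint8(2)
                    v = x[i, 2 * r + 1, 2 * s + 1, ch]
                    if v > best:
                        best = v
                        bi = np.uint8(3)
                    out[i, r, s, ch] = best
                    idx[i, r, s, ch] = bi


@njit(cache=True, fastmath=True)
def _maxpool2_bwd(dy, idx, dx):
    n, h2, w2, c = dy.shape
    dx[:] = 0.0
    for i in range(n):
        for r in range(h2):
            for s in range(w2):
                for ch in range(c):
                    bi = idx[i, r, s, ch]
                    dx[i, 2 * r + bi // 2, 2 * s + bi % 2, ch] = dy[i, r, s, ch]


@njit(cache=True, fastmath=True)
def _col2im_add(dcols, dxpad):
    # dcols: (n, H, W, 9, c); dxpad: (n, H+2, W+2, c)
    n, H, W, _, c = dcols.shape
    for i in range(n):
        for r in range(H):
            for s in range(W):
                for k in range(9):
                    ki = k // 3
                    kj = k - 3 * ki
                    for ch in range(c):
                        dxpad[i, r + ki, s + kj, ch] += dcols[i, r, s, k, ch]


def maxpool2_fwd(x):
    n, H, W, c = x.shape
    h2, w2 = H // 2, W // 2
    out = np.empty((n, h2, w2, c), dtype=np.float32)
    idx = np.empty((n, h2, w2, c), dtype=np.uint8)
    _maxpool2_fwd(x, out, idx)
    return out, idx


def maxpool2_bwd(dy, idx, dx):
    _maxpool2_bwd(dy, idx, dx)
    return dx


def col2im_add(dcols, dxpad):
    _col2im_add(dcols, dxpad)
    return dxpad
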