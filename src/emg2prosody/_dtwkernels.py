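"""Numba kernels for dynamic time warping (Euclidean local cost)."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _dist(a, b, i, j):
    s = 0.0
    for k in range(a.shape[1]):
        d = a[i, k] - b[j, k]
        s += d * d
    return np.sqrt(s)


@njit(cache=True)
def full_dp(a, b):
    """Full DP table. Returns (cost, steps) where steps[i, j] encodes the
    predecessor: 2 = (1,1), 1 = (1,0), 0 = (0,1).  Ties prefer the diagonal,
    then (1,0)."""
    n, m = a.shape[0], b.shape[0]
    D = np.empty((n, m))
    steps = np.zeros((n, m), dtype=np.int8)
    D[0, 0] = _dist(a, b, 0, 0)
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + _dist(a, b, 0, j)
        steps[0, j] = 0
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + _dist(a, b, i, 0)
        steps[i, 0] = 1
        for j in range(1, m):
            best = D[i - 1, j - 1]
            st = 2
            if D[i - 1, j] < best:
                best = D[i - 1, j]
                st = 1
            if D[i, j - 1] < best:
                best = D[i, j - 1]
                st = 0
            D[i, j] = best + _dist(a, b, i, j)
            steps[i, j] = st
    return D[n - 1, m - 1], steps


@njit(cache=True)
def forward_row(a, b, row0, row1):
    """Cumulative-cost forward pass keeping two rows; returns the last row.

    ``row0``/``row1`` are caller-allocated scratch of length len(b), so the
    caller can meter memory.
    """
    n, m = a.shape[0], b.shape[0]
    row0[0] = _dist(a, b, 0, 0)
    for j in range(1, m):
        row0[j] = row0[j - 1] + _dist(a, b, 0, j)
    if n == 1:
        return row0
    cur, prev = row1, row0
    for i in range(1, n):
        cur[0] = prev[0] + _dist(a, b, i, 0)
        for j in range(1, m):
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = best + _dist(a, b, i, j)
        prev, cur = cur, prev
    return prev
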