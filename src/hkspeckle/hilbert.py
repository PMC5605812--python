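"""Hilbert space-filling curve vertices and arc-length mapping.

Vertices are generated with Skilling's transpose algorithm (vectorized over
all indices), giving the locality-preserving traversal of the 2^(order*dim)
grid cells: consecutive vertices always differ by one grid step along a
single axis.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np

__all__ = ["hilbert_vertices", "hilbert_map"]

log = logging.getLogger(__name__)


@lru_cache(maxsize=4)
def _cached_vertices(order: int, dim: int) -> np.ndarray:
    return _compute_vertices(order, dim)


def hilbert_vertices(order: int, dim: int) -> np.ndarray:
    """Integer grid coordinates of the order-``order`` Hilbert curve in ``dim`` D.

    Returns an array of shape ``(2**(order*dim), dim)``; row ``h`` is the grid
    position (each coordinate in ``[0, 2**order)``) of curve index ``h``.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")
    return _cached_vertices(order, dim)


def _compute_vertices(order: int, dim: int) -> np.ndarray:
    n_pts = 1 << (order * dim)
    h = np.arange(n_pts, dtype=np.uint64)

    # transpose form: bit j of X[i] is bit (j*dim + dim-1-i) of h
    X = np.zeros((dim, n_pts), dtype=np.uint64)
    for j in range(order):
        for i in range(dim):
            src_bit = np.uint64(j * dim + dim - 1 - i)
            X[i] |= ((h >> src_bit) & np.uint64(1)) << np.uint64(j)

    # Skilling: transpose -> axes
    t = X[dim - 1] >> np.uint64(1)
    for i in range(dim - 1, 0, -1):
        X[i] ^= X[i - 1]
    X[0] ^= t
    Q = np.uint64(2)
    N = np.uint64(1) << np.uint64(order)
    while Q != N:
        P = Q - np.uint64(1)
        for i in range(dim - 1, -1, -1):
            hi_set = (X[i] & Q) != 0
            X[0] = np.where(hi_set, X[0] ^ P, X[0])
            tt = np.where(hi_set, np.uint64(0), (X[0] ^ X[i]) & P)
            X[0] ^= tt
            X[i] ^= tt
        Q <<= np.uint64(1)
    return X.T.astype(np.int64)


def hilbert_map(
    positions_1d: np.ndarray,
    order: int,
    dim: int,
    side: float,
) -> np.ndarray:
    """Map 1D arc-length positions onto the Hilbert curve in ``[0, side]**dim``.

    The curve's vertices are joined by equal-length straight segments; a
    position a fraction ``t`` along the total length is linearly interpolated
    within its segment.  Positions beyond the curve length are wrapped modulo
    the total length (and logged).
    """
    pos = np.asarray(positions_1d, dtype=float)
    if np.any(pos < 0):
        raise ValueError("1D positions must be nonnegative")
    verts = hilbert_vertices(order, dim).astype(float)
    n_seg = len(verts) - 1
    scale = side / ((1 << order) - 1)
    verts *= scale
    seg_len = scale  # adjacent vertices differ by one grid step
    total = n_seg * seg_len

    overflow = pos >= total
    if np.any(overflow):
        log.info("%d/%d positions exceeded curve length %.4g; wrapped", int(overflow.sum()), pos.size, total)
        pos = np.mod(pos, total)

    idx = np.minimum((pos / seg_len).astype(int), n_seg - 1)
    frac = pos / seg_len - idx
    return verts[idx] + frac[:, None] * (verts[idx + 1] - verts[idx])


def curve_length(order: int, dim: int, side: float) -> float:
    """Total arc length of the order-``order`` Hilbert curve scaled to ``side``."""
    n_seg = (1 << (order * dim)) - 1
    return n_seg * side / ((1 << order) - 1)
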