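"""Minimum-image neighbor searches under an orthorhombic periodic box.

Two interchangeable backends are provided: an O(N²) brute-force search and a
periodic k-d tree (``scipy.spatial.cKDTree`` with ``boxsize``).  The brute
route doubles as the correctness oracle for the accelerated one.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .geometry import minimum_image_distance


def _wrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.mod(coords, box)


def _check_cutoff(box: np.ndarray, cutoff: float) -> None:
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff > min(box) / 2:
        raise ValueError(
            f"cutoff {cutoff} exceeds half the smallest box length ({min(box) / 2})"
        )


def cross_pairs(
    a: np.ndarray,
    b: np.ndarray,
    box: np.ndarray,
    cutoff: float,
    method: str = "kdtree",
) -> np.ndarray:
    """All (i, j) with min-image distance(a[i], b[j]) <= cutoff, shape (n_pairs, 2)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    box = np.asarray(box, dtype=float)[: a.shape[1]]
    _check_cutoff(box, cutoff)
    if a.size == 0 or b.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    if method == "brute":
        dist = minimum_image_distance(a, b, box)
        ii, jj = np.nonzero(dist <= cutoff)
        return np.column_stack([ii, jj]).astype(np.int64)
    if method == "kdtree":
        ta = cKDTree(_wrap(a, box), boxsize=box)
        tb = cKDTree(_wrap(b, box), boxsize=box)
        pairs = [
            (i, j)
            for i, neigh in enumerate(ta.query_ball_tree(tb, r=cutoff))
            for j in neigh
        ]
        out = np.array(pairs, dtype=np.int64).reshape(-1, 2)
        return out[np.lexsort((out[:, 1], out[:, 0]))]
    raise ValueError(f"unknown method {method!r}")


def indices_within(
    point: np.ndarray,
    coords: np.ndarray,
    box: np.ndarray,
    cutoff: float,
    method: str = "kdtree",
) -> np.ndarray:
    """Sorted indices of ``coords`` within ``cutoff`` of a single point."""
    point = np.asarray(point, dtype=float).reshape(1, -1)
    pairs = cross_pairs(point, coords, box, cutoff, method=method)
    return np.sort(pairs[:, 1])


def any_within(
    a: np.ndarray,
    b: np.ndarray,
    box: np.ndarray,
    cutoff: float,
    method: str = "kdtree",
) -> bool:
    return cross_pairs(a, b, box, cutoff, method=method).shape[0] > 0


def min_cross_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    """Smallest min-image distance between two point sets (brute force)."""
    return float(minimum_image_distance(a, b, box).min())
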