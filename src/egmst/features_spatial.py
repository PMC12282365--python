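"""Spatial gradients of activation/repolarization fields over a 3D point cloud.

The gradient at a point is the mean of |value difference| / distance over all
neighbouring points within a 10-mm (closed) Euclidean ball, computed per map.
High gradients of activation time mark conduction slowing/isochronal crowding;
high repolarization/ARI gradients mark repolarization dispersion.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["DEFAULT_RADIUS_MM", "spatial_gradient", "spatial_gradient_bruteforce"]

DEFAULT_RADIUS_MM = 10.0


def spatial_gradient(xyz: np.ndarray, values: np.ndarray,
                     radius_mm: float = DEFAULT_RADIUS_MM) -> np.ndarray:
    """Per-point mean absolute change per mm over neighbours within radius.

    Parameters
    ----------
    xyz : (n, 3) coordinates in mm.
    values : (n,) field values in ms; NaN marks missing.
    radius_mm : neighbourhood radius; the ball is closed (ties included).

    Returns
    -------
    (n,) array, NaN where the value is missing or no neighbour with a value
    exists (including duplicate-coordinate-only neighbourhoods: zero distances
    are excluded).
    """
    xyz = np.asarray(xyz, dtype=float)
    values = np.asarray(values, dtype=float)
    n = xyz.shape[0]
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    out = np.full(n, np.nan)
    valid = np.isfinite(values)
    if valid.sum() < 2:
        return out
    idx = np.nonzero(valid)[0]
    pts = xyz[idx]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=radius_mm, output_type="ndarray")  # dist <= r
    sums = np.zeros(idx.size)
    counts = np.zeros(idx.size, dtype=int)
    if pairs.size:
        i, j = pairs[:, 0], pairs[:, 1]
        d = np.linalg.norm(pts[i] - pts[j], axis=1)
        keep = d > 0  # duplicate coordinates are excluded
        i, j, d = i[keep], j[keep], d[keep]
        g = np.abs(values[idx[i]] - values[idx[j]]) / d
        np.add.at(sums, i, g)
        np.add.at(sums, j, g)
        np.add.at(counts, i, 1)
        np.add.at(counts, j, 1)
    has = counts > 0
    out[idx[has]] = sums[has] / counts[has]
    return out


def spatial_gradient_bruteforce(xyz: np.ndarray, values: np.ndarray,
                                radius_mm: float = DEFAULT_RADIUS_MM) -> np.ndarray:
    """All-pairs reference implementation (O(n^2)); for validation only."""
    xyz = np.asarray(xyz, dtype=float)
    values = np.asarray(values, dtype=float)
    n = xyz.shape[0]
    out = np.full(n, np.nan)
    for p in range(n):
        if not np.isfinite(values[p]):
            continue
        acc, cnt = 0.0, 0
        for q in range(n):
            if q == p or not np.isfinite(values[q]):
                continue
            d = float(np.linalg.norm(xyz[p] - xyz[q]))
            if 0 < d <= radius_mm:
                acc += abs(values[p] - values[q]) / d
                cnt += 1
        if cnt:
            out[p] = acc / cnt
    return out
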