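"""Exact caliper geometry on planar point sets.

Feret (caliper) diameters are computed on the convex hull of a point set:
the maximum Feret diameter (FD) by rotating calipers over antipodal vertex
pairs, the minimum Feret diameter (mFD) as the exact minimal width, which
for a convex polygon is always attained perpendicular to one of its edges.

Particle masks are represented by the corners of their boundary pixels
(each pixel a closed unit square), so an axis-aligned w x h pixel rectangle
has FD = sqrt(w^2 + h^2) and mFD = min(w, h) exactly.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "boundary_corner_points",
    "convex_hull_vertices",
    "max_feret",
    "min_feret",
    "feret_diameters",
]

_CORNER_OFFSETS = np.array(
    [[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]], dtype=np.float64
)


def boundary_corner_points(mask: np.ndarray) -> np.ndarray:
    """Corners of the boundary pixels of a binary mask, as (row, col) floats.

    Pixel (r, c) occupies the closed square [r-0.5, r+0.5] x [c-0.5, c+0.5].
    Interior pixels are dropped first; their corners cannot lie on the hull.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.empty((0, 2), dtype=np.float64)
    interior = ndi.binary_erosion(mask, structure=np.ones((3, 3), bool), border_value=0)
    boundary = mask & ~interior
    centers = np.argwhere(boundary).astype(np.float64)
    pts = (centers[:, None, :] + _CORNER_OFFSETS[None, :, :]).reshape(-1, 2)
    return np.unique(pts, axis=0)


def convex_hull_vertices(points: np.ndarray) -> np.ndarray:
    """Hull vertices in counter-clockwise order; degenerate sets pass through."""
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 3:
        return points
    try:
        hull = ConvexHull(points)
    except QhullError:  # collinear input
        order = np.lexsort((points[:, 1], points[:, 0]))
        return points[order[[0, -1]]]
    return points[hull.vertices]


def _cross(o: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def max_feret(points: np.ndarray) -> float:
    """Maximum caliper (Feret) diameter by rotating calipers on the hull."""
    hull = convex_hull_vertices(points)
    n = len(hull)
    if n == 0:
        return 0.0
    if n == 1:
        return 0.0
    if n == 2:
        return float(np.hypot(*(hull[0] - hull[1])))
    best = 0.0
    k = 1
    for i in range(n):
        j = (i + 1) % n
        # advance the antipodal point while the supported triangle area grows
        while abs(_cross(hull[i], hull[j], hull[(k + 1) % n])) > abs(
            _cross(hull[i], hull[j], hull[k])
        ):
            k = (k + 1) % n
        d1 = np.hypot(*(hull[k] - hull[i]))
        d2 = np.hypot(*(hull[k] - hull[j]))
        best = max(best, d1, d2)
    return float(best)


def min_feret(points: np.ndarray) -> float:
    """Minimal caliper width: smallest slab, over hull edge orientations."""
    hull = convex_hull_vertices(points)
    n = len(hull)
    if n <= 1:
        return 0.0
    if n == 2:
        return 0.0
    best = np.inf
    for i in range(n):
        j = (i + 1) % n
        edge = hull[j] - hull[i]
        norm = np.hypot(edge[0], edge[1])
        if norm == 0.0:
            continue
        # perpendicular distance of every vertex from the edge's line
        rel = hull - hull[i]
        dist = np.abs(rel[:, 0] * edge[1] - rel[:, 1] * edge[0]) / norm
        best = min(best, float(dist.max()))
    return float(best) if np.isfinite(best) else 0.0


def feret_diameters(points: np.ndarray) -> tuple[float, float]:
    """(FD, mFD) of a point set; FD >= mFD by construction."""
    return max_feret(points), min_feret(points)
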