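"""Small geometric helpers shared across modules.

Conventions used throughout the package:

- pixel coordinates are 0-based ``(u, v) = (column, row)``, sub-pixel allowed;
- rectangles are ``(u, v, w, h)`` with the *top-left* corner at ``(u, v)`` and
  half-open extent, i.e. they contain pixels with ``u <= x < u + w``;
- angles are radians, measured with ``atan2(dv, du)`` in image coordinates
  (v axis pointing down), so a positive rotation turns u toward v.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import polygon2mask

__all__ = [
    "wrap_angle",
    "circular_median",
    "rect_center",
    "rect_contains",
    "rect_clip",
    "rect_scale",
    "rotation_matrix",
    "hull_vertices",
    "point_in_hull",
    "convex_hull_mask",
    "rect_mask",
]


def wrap_angle(a):
    """Wrap angle(s) to the interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    wrapped = np.mod(-a + np.pi, 2.0 * np.pi)
    out = -(wrapped - np.pi)
    return float(out) if out.ndim == 0 else out


def circular_median(angles):
    """Median direction of a set of angles.

    Returns the sample angle minimising the summed absolute circular
    deviation from all samples (ties broken by sample order), wrapped to
    (-pi, pi].  This is the natural robust location estimate on the circle
    and coincides with the ordinary median for tightly clustered samples.
    """
    a = np.atleast_1d(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("circular_median of empty set")
    if a.size == 1:
        return wrap_angle(a[0])
    dev = np.abs(wrap_angle(a[:, None] - a[None, :])).sum(axis=1)
    return wrap_angle(a[int(np.argmin(dev))])


def rect_center(rect):
    u, v, w, h = rect
    return np.array([u + w / 2.0, v + h / 2.0])


def rect_contains(rect, points):
    """Half-open membership test; ``points`` is (n, 2) array of (u, v)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    u, v, w, h = rect
    inside = (
        (pts[:, 0] >= u)
        & (pts[:, 0] < u + w)
        & (pts[:, 1] >= v)
        & (pts[:, 1] < v + h)
    )
    return inside


def rect_clip(rect, shape_hw):
    """Clip a rect to an image of shape (H, W); returns integer rect or None."""
    H, W = shape_hw[:2]
    u, v, w, h = rect
    u0 = int(np.floor(max(u, 0)))
    v0 = int(np.floor(max(v, 0)))
    u1 = int(np.ceil(min(u + w, W)))
    v1 = int(np.ceil(min(v + h, H)))
    if u1 <= u0 or v1 <= v0:
        return None
    return (u0, v0, u1 - u0, v1 - v0)


def rect_scale(rect, factor):
    """Scale a rect about its own center."""
    u, v, w, h = rect
    cu, cv = u + w / 2.0, v + h / 2.0
    nw, nh = w * factor, h * factor
    return (cu - nw / 2.0, cv - nh / 2.0, nw, nh)


def rotation_matrix(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def hull_vertices(points):
    """Convex-hull vertices of (n, 2) points, or None when degenerate."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        return None
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return None
    return pts[hull.vertices]


def point_in_hull(point, points, tol=1e-9):
    """True if ``point`` lies inside the convex hull of ``points``.

    Degenerate point sets (fewer than 3 points, collinear) give False.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        return False
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return False
    eq = hull.equations
    p = np.asarray(point, dtype=float)
    return bool(np.all(eq[:, :2] @ p + eq[:, 2] <= tol))


def convex_hull_mask(shape_hw, points):
    """Boolean mask of the convex hull of (u, v) points, or None if degenerate."""
    verts = hull_vertices(points)
    if verts is None:
        return None
    # polygon2mask expects (row, col) vertex order
    mask = polygon2mask(shape_hw[:2], verts[:, ::-1])
    if not mask.any():
        return None
    return mask


def rect_mask(shape_hw, rect):
    """Boolean mask of a rect clipped to the image; all-False if no overlap."""
    mask = np.zeros(shape_hw[:2], dtype=bool)
    clipped = rect_clip(rect, shape_hw)
    if clipped is not None:
        u0, v0, w, h = clipped
        mask[v0 : v0 + h, u0 : u0 + w] = True
    return mask
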