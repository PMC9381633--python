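"""Planar geometry primitives shared by the imaging and EM modules.

All routines operate on plain ``(N, 2)`` float arrays of ``(x, y)``
coordinates; units are whatever the caller uses (µm for light microscopy,
nm for EM annotations).
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon


def shoelace_area(vertices: np.ndarray) -> float:
    """Area of a simple polygon by the shoelace formula.

    Parameters
    ----------
    vertices : (N, 2) array
        Polygon vertices in order (either orientation); the polygon is
        closed implicitly.

    Returns
    -------
    float
        Absolute enclosed area in squared input units.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValueError("polygon requires an (N>=3, 2) vertex array")
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def validate_polygon(vertices: np.ndarray) -> None:
    """Raise ``ValueError`` unless the vertices form a simple polygon of
    positive area."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValueError("polygon requires an (N>=3, 2) vertex array")
    poly = Polygon(v)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("polygon is degenerate or self-intersecting")


def point_to_polyline_distance(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Minimum Euclidean distance from each point to an open polyline.

    The distance to each segment is the exact point-to-segment distance
    (perpendicular foot if it falls inside the segment, else the nearer
    endpoint); the polyline distance is the minimum over segments.

    Parameters
    ----------
    points : (P, 2) array
    polyline : (M >= 2, 2) array of consecutive vertices

    Returns
    -------
    (P,) array of distances.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    line = np.asarray(polyline, dtype=float)
    if line.ndim != 2 or line.shape[1] != 2 or line.shape[0] < 2:
        raise ValueError("polyline requires an (M>=2, 2) vertex array")
    a = line[:-1]                      # (S, 2) segment starts
    d = line[1:] - a                   # (S, 2) segment vectors
    len2 = np.einsum("ij,ij->i", d, d)  # (S,)
    if np.any(len2 == 0) and np.all(len2 == 0):
        # degenerate polyline of coincident vertices: point distances
        return np.linalg.norm(pts[:, None, :] - a[None, :, :], axis=2).min(axis=1)
    # projection parameter of each point onto each segment, clipped to [0, 1]
    w = pts[:, None, :] - a[None, :, :]            # (P, S, 2)
    t = np.einsum("psj,sj->ps", w, d) / np.where(len2 == 0, 1.0, len2)
    t = np.clip(t, 0.0, 1.0)
    foot = a[None, :, :] + t[:, :, None] * d[None, :, :]
    dist = np.linalg.norm(pts[:, None, :] - foot, axis=2)
    return dist.min(axis=1)


def points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Boolean mask of points strictly inside or on a simple polygon."""
    from matplotlib.path import Path

    v = np.asarray(vertices, dtype=float)
    # a closed Path treats its final vertex as the close target, so the
    # first vertex must be repeated explicitly
    path = Path(np.vstack([v, v[:1]]), closed=True)
    return path.contains_points(np.atleast_2d(points), radius=1e-9)
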