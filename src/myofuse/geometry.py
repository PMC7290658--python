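"""Planar geometry primitives used across simulation, rendering and ROI assignment.

Coordinate convention (shared by the whole package): the pixel grid is 0-based
with origin at the top-left corner, x = column and y = row; polygon vertices
live in the same continuous frame, and the sample point of pixel (row, col) is
its centre ``(col + 0.5, row + 0.5)``.

Point-in-polygon uses the even-odd (ray crossing) rule with points on the
boundary counting as inside, so a nucleus centroid sitting exactly on a drawn
ROI edge is never silently dropped.
"""

import numpy as np

__all__ = [
    "polygon_area",
    "polygon_centroid",
    "points_in_polygon",
    "point_segment_distance",
    "segment_segment_distance",
    "capsule_polygon",
]


def polygon_area(poly: np.ndarray) -> float:
    """Unsigned area of a simple polygon (shoelace formula)."""
    p = np.asarray(poly, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_centroid(poly: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon; falls back to the vertex mean for
    degenerate (zero-area) input."""
    p = np.asarray(poly, dtype=float)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        return p.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def points_in_polygon(points: np.ndarray, poly: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Even-odd point-in-polygon test, boundary inclusive.

    Parameters
    ----------
    points : (N, 2) array of (x, y)
    poly : (M, 2) array of ordered vertices (closed implicitly)
    tol : absolute tolerance for the on-boundary test

    Returns
    -------
    (N,) boolean array; True when inside or on an edge.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.asarray(poly, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    on_edge = np.zeros(len(pts), dtype=bool)
    n = poly.shape[0]
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        dx, dy = x2 - x1, y2 - y1
        seg2 = dx * dx + dy * dy
        if seg2 < tol * tol:
            on_edge |= (np.abs(x - x1) <= tol) & (np.abs(y - y1) <= tol)
            continue
        # boundary: zero cross product and projection parameter within [0, 1]
        cross = (x - x1) * dy - (y - y1) * dx
        t = ((x - x1) * dx + (y - y1) * dy) / seg2
        on_edge |= (np.abs(cross) <= tol * np.sqrt(seg2)) & (t >= -tol) & (t <= 1 + tol)
        # half-open crossing rule is robust to vertices lying on the ray
        crosses = (y1 > y) != (y2 > y)
        if crosses.any():
            with np.errstate(divide="ignore", invalid="ignore"):
                x_int = x1 + (y - y1) / dy * dx
            inside ^= crosses & (x < x_int)
    return inside | on_edge


def point_segment_distance(p, a, b) -> float:
    """Distance from point p to segment ab."""
    p, a, b = (np.asarray(v, dtype=float) for v in (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.hypot(*(p - a)))
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
    return float(np.hypot(*(p - (a + t * ab))))


def points_segment_distance(points: np.ndarray, a, b) -> np.ndarray:
    """Vectorized distance from many points to one segment."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.hypot(pts[:, 0] - a[0], pts[:, 1] - a[1])
    t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.hypot(pts[:, 0] - proj[:, 0], pts[:, 1] - proj[:, 1])


def segment_segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between segments p1q1 and p2q2."""
    p1, q1, p2, q2 = (np.asarray(v, dtype=float) for v in (p1, q1, p2, q2))

    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1, d2 = orient(p2, q2, p1), orient(p2, q2, q1)
    d3, d4 = orient(p1, q1, p2), orient(p1, q1, q2)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return 0.0  # proper intersection
    return min(
        point_segment_distance(p1, p2, q2),
        point_segment_distance(q1, p2, q2),
        point_segment_distance(p2, p1, q1),
        point_segment_distance(q2, p1, q1),
    )


def capsule_polygon(center, angle: float, length: float, width: float, n_cap: int = 10) -> np.ndarray:
    """Simple polygon approximating a capsule (a segment dilated by width/2).

    The polygon is the convex hull of two semicircular caps sampled with
    ``n_cap`` intervals each, traversed counter-clockwise; it is simple by
    construction and inscribed in the true capsule (chords cut inwards by at
    most ``width/2 * (1 - cos(pi / (2 n_cap)))``, under 2 % for n_cap = 10).
    """
    c = np.asarray(center, dtype=float)
    u = np.array([np.cos(angle), np.sin(angle)])
    e1 = c - 0.5 * length * u
    e2 = c + 0.5 * length * u
    h = 0.5 * width
    a_right = np.linspace(angle - np.pi / 2, angle + np.pi / 2, n_cap + 1)
    a_left = np.linspace(angle + np.pi / 2, angle + 3 * np.pi / 2, n_cap + 1)
    right = e2 + h * np.column_stack([np.cos(a_right), np.sin(a_right)])
    left = e1 + h * np.column_stack([np.cos(a_left), np.sin(a_left)])
    return np.vstack([right, left])
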