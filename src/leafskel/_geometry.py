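"""Small planar-geometry primitives shared across modules.

Coordinate convention (used everywhere in this package): x = column,
y = row, origin at the top-left corner, y increases downward.  "Above"
therefore means a *smaller* row index.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "angle_between",
    "turning_angle",
    "arch_test",
    "point_segment_distance",
    "polyline_length",
    "circle_segment_intersections",
]


def angle_between(u, v) -> float:
    """Angle between two 2-vectors in degrees, in [0, 180].

    Raises ValueError on a zero vector.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = float(np.hypot(*u))
    nv = float(np.hypot(*v))
    if nu == 0.0 or nv == 0.0:
        raise ValueError("angle_between undefined for a zero vector")
    c = float(np.dot(u, v)) / (nu * nv)
    c = min(1.0, max(-1.0, c))
    return float(np.degrees(np.arccos(c)))


def turning_angle(p0, p1, p2) -> float:
    """Angle in degrees between directions p0->p1 and p1->p2 (0 = straight)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    return angle_between(p1 - p0, p2 - p1)


def arch_test(p0, p1, p2, straight_tol: float = 20.0) -> bool:
    """Convexity check for a consecutive keypoint triple.

    True when the middle vertex does not fall below the chord of its
    neighbours (row coordinates: "below" means a larger y), or when the
    triple is nearly collinear — direction change at the middle vertex at
    most ``straight_tol`` degrees.  The chord condition encodes the
    gravity-arch shape of regular leaves; the collinearity allowance
    covers vertical or near-vertical runs, where a chord-in-x test is
    ill-posed and a straight chain is degenerate-convex.

    Implemented as a direction-signed cross product, which equals the
    chord test whenever the middle x lies between the endpoint x's.
    """
    x0, y0 = float(p0[0]), float(p0[1])
    x1, y1 = float(p1[0]), float(p1[1])
    x2, y2 = float(p2[0]), float(p2[1])
    dx = x2 - x0
    # cross = (p2-p0) x (p1-p0); above the chord <=> cross/dx <= 0
    cross = dx * (y1 - y0) - (y2 - y0) * (x1 - x0)
    if dx != 0.0 and cross * np.sign(dx) <= 0.0:
        return True
    u = (x1 - x0, y1 - y0)
    v = (x2 - x1, y2 - y1)
    if (u[0] == 0 and u[1] == 0) or (v[0] == 0 and v[1] == 0):
        return True
    return angle_between(u, v) <= straight_tol


def point_segment_distance(points: np.ndarray, a, b) -> np.ndarray:
    """Distance of each point (N x 2) to the segment ab."""
    points = np.atleast_2d(np.asarray(points, float))
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.hypot(*(points - a).T)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.hypot(*(points - proj).T)


def polyline_length(vertices: np.ndarray) -> float:
    """Total Euclidean length of an ordered vertex list."""
    v = np.asarray(vertices, float)
    if len(v) < 2:
        return 0.0
    return float(np.hypot(*np.diff(v, axis=0).T).sum())


def circle_segment_intersections(center, radius: float, a, b) -> list[tuple[float, float]]:
    """Intersection points of a circle with the closed segment ab.

    Tangency yields a single point; endpoints on the circle are included.
    """
    cx, cy = float(center[0]), float(center[1])
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = b - a
    f = a - np.array([cx, cy])
    A = float(d @ d)
    if A == 0.0:
        return []
    B = 2.0 * float(f @ d)
    C = float(f @ f) - radius * radius
    disc = B * B - 4.0 * A * C
    if disc < 0.0:
        return []
    sq = float(np.sqrt(disc))
    out: list[tuple[float, float]] = []
    ts = [(-B - sq) / (2 * A)] if disc == 0.0 else [(-B - sq) / (2 * A), (-B + sq) / (2 * A)]
    for t in ts:
        if -1e-12 <= t <= 1.0 + 1e-12:
            p = a + min(max(t, 0.0), 1.0) * d
            out.append((float(p[0]), float(p[1])))
    return out
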