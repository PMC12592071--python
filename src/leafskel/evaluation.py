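"""Skeleton accuracy metrics: curvature error, leaf recall and the
tip-miss diagnostic.

The curvature error compares the analytic curvature of the true midrib
curve, kappa = |y''| / (1 + y'^2)^{3/2}, with a discrete polyline
curvature built from interior vertex angles,
kappa_i = |theta_{i-1} + theta_{i+1} - 2 theta_i| / (d_{i-1,i} + d_{i,i+1}),
where theta_i is the interior angle (radians) at vertex i and d the
segment length.  For a straight polyline every theta is pi, so the
second difference — and hence the curvature — vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from ._geometry import point_segment_distance
from .sampling import SeedPointSet
from .tracing import LeafPolyline, PlantSkeleton

__all__ = [
    "TrueCurve",
    "EvalReport",
    "curve_curvature",
    "polyline_curvature",
    "curvature_error",
    "leaf_recall",
    "tip_miss",
]


@dataclass
class TrueCurve:
    """Twice-differentiable ground-truth midrib graph y(x) on [x_lo, x_hi].

    ``y``, ``dy`` and ``ddy`` are scalar callables.  For externally
    supplied dense point lists use :meth:`from_points`, which
    differentiates by local quadratic fits.
    """

    y: Callable[[float], float]
    dy: Callable[[float], float]
    ddy: Callable[[float], float]
    domain: tuple[float, float]

    @classmethod
    def from_polynomial(cls, coeffs: Sequence[float], domain: tuple[float, float]) -> "TrueCurve":
        """From highest-degree-first polynomial coefficients."""
        p = np.polynomial.Polynomial(list(reversed(list(coeffs))))
        d1, d2 = p.deriv(1), p.deriv(2)
        return cls(y=lambda x: float(p(x)), dy=lambda x: float(d1(x)),
                   ddy=lambda x: float(d2(x)), domain=(float(domain[0]), float(domain[1])))

    @classmethod
    def from_points(cls, xy: np.ndarray, window: int = 7) -> "TrueCurve":
        """From a dense (x, y) sample, via moving local quadratic fits."""
        xy = np.asarray(xy, float)
        order = np.argsort(xy[:, 0])
        xs, ys = xy[order, 0], xy[order, 1]
        half = max(2, window // 2)

        def _fit(x: float) -> np.ndarray:
            i = int(np.searchsorted(xs, x))
            lo, hi = max(0, i - half), min(len(xs), i + half + 1)
            return np.polyfit(xs[lo:hi], ys[lo:hi], deg=min(2, hi - lo - 1))

        return cls(
            y=lambda x: float(np.polyval(_fit(x), x)),
            dy=lambda x: float(np.polyval(np.polyder(_fit(x)), x)),
            ddy=lambda x: float(np.polyval(np.polyder(_fit(x), 2), x)) if len(_fit(x)) > 2 else 0.0,
            domain=(float(xs[0]), float(xs[-1])),
        )


@dataclass
class EvalReport:
    """Per-plant evaluation summary."""

    curvature_error: float | None
    leaf_recall: float
    tip_missed: list[bool]

    def to_dict(self) -> dict:
        return {
            "curvature_error": self.curvature_error,
            "leaf_recall": self.leaf_recall,
            "tip_missed": list(map(bool, self.tip_missed)),
        }


def curve_curvature(curve: TrueCurve, x: float) -> float:
    """Analytic curvature |y''| / (1 + y'^2)^{3/2} at x, 1/px."""
    lo, hi = curve.domain
    if not (lo - 1e-9 <= x <= hi + 1e-9):
        raise ValueError(f"x={x} outside curve domain [{lo}, {hi}]")
    dy = curve.dy(x)
    return abs(curve.ddy(x)) / (1.0 + dy * dy) ** 1.5


def _interior_angle(a, b, c) -> float:
    """Interior angle at b (radians, in [0, pi])."""
    u = np.asarray(a, float) - b
    v = np.asarray(c, float) - b
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu == 0 or nv == 0:
        raise ValueError("degenerate polyline vertex")
    cos = np.clip(float(u @ v) / (nu * nv), -1.0, 1.0)
    return float(np.arccos(cos))


def polyline_curvature(polyline: LeafPolyline | np.ndarray, i: int, signed: bool = False) -> float:
    """Discrete curvature at interior vertex ``i`` (0-based), 1/px.

    Needs interior angles at i-1, i and i+1, so ``2 <= i <= N-3``.
    Interior angles are measured in radians; the magnitude of the
    second difference is returned unless ``signed`` is set.
    """
    kp = polyline.keypoints if isinstance(polyline, LeafPolyline) else np.asarray(polyline, float)
    n = len(kp)
    if not (2 <= i <= n - 3):
        raise IndexError(f"vertex {i} lacks the full curvature stencil (need 2 <= i <= {n - 3})")
    th = [_interior_angle(kp[j - 1], kp[j], kp[j + 1]) for j in (i - 1, i, i + 1)]
    d = np.hypot(*(kp[i] - kp[i - 1])) + np.hypot(*(kp[i + 1] - kp[i]))
    val = (th[0] + th[2] - 2.0 * th[1]) / float(d)
    return val if signed else abs(val)


def curvature_error(
    curve: TrueCurve,
    polyline: LeafPolyline | np.ndarray,
    to_domain: Callable[[np.ndarray], float] | None = None,
) -> float:
    """Mean absolute difference between analytic and discrete curvature
    over the polyline's interior vertices.

    ``to_domain`` maps a vertex (x, y) to the curve's abscissa; by
    default the vertex x-coordinate is used.  Vertices that fall outside
    the curve domain are skipped; an empty evaluation set is an error.
    """
    kp = polyline.keypoints if isinstance(polyline, LeafPolyline) else np.asarray(polyline, float)
    if len(kp) < 5:
        raise ValueError("need at least five vertices for the curvature stencil")
    lo, hi = curve.domain
    diffs: list[float] = []
    for i in range(2, len(kp) - 2):
        x = float(kp[i, 0]) if to_domain is None else float(to_domain(kp[i]))
        if not (lo - 1e-9 <= x <= hi + 1e-9):
            continue
        diffs.append(abs(curve_curvature(curve, x) - polyline_curvature(kp, i)))
    if not diffs:
        raise ValueError("no polyline vertex falls inside the curve domain")
    return float(np.mean(diffs))


def leaf_recall(skeleton: PlantSkeleton | int, gt_count: int) -> float:
    """Detected leaves over ground-truth leaves, percent.

    Over-segmentation is reported as is (values above 100 are possible).
    """
    if gt_count < 1:
        raise ValueError("gt_count must be >= 1")
    detected = skeleton if isinstance(skeleton, int) else len(skeleton.leaves)
    return 100.0 * detected / gt_count


def tip_miss(gt_midrib: np.ndarray, points: SeedPointSet, corridor: float = 5.0) -> bool:
    """True iff no sampled point lies within ``corridor`` px of the
    outermost 20% (by arc length from the tip) of the true midrib.

    Narrow leaf tips can lose all interior pixels to boundary erosion,
    leaving the tip sector unsampled; this flags that failure mode.
    """
    mid = np.asarray(gt_midrib, float).reshape(-1, 2)
    if len(mid) < 2:
        raise ValueError("ground-truth midrib needs at least two vertices")
    seg = np.hypot(*np.diff(mid, axis=0).T)
    total = float(seg.sum())
    if total == 0.0:
        raise ValueError("degenerate ground-truth midrib")
    cut = 0.2 * total
    # walk from the tip (vertex 0) until 20% of arc length is covered
    tip_segs: list[tuple[np.ndarray, np.ndarray]] = []
    acc = 0.0
    for k, ds in enumerate(seg):
        if acc >= cut:
            break
        if acc + ds <= cut or ds == 0.0:
            tip_segs.append((mid[k], mid[k + 1]))
        else:
            t = (cut - acc) / ds
            tip_segs.append((mid[k], mid[k] + t * (mid[k + 1] - mid[k])))
        acc += ds
    pts = points.points
    if len(pts) == 0:
        return True
    for a, b in tip_segs:
        if (point_segment_distance(pts, a, b) <= corridor).any():
            return False
    return True
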