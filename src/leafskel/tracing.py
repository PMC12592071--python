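"""Keypoint connection: turn sampled seed points into one midrib polyline
per leaf.

Two tracers share the same outer loop (farthest unvisited point = next
leaf tip) but differ in how the chain grows:

* **random morphology** (top view): from the tip inward, a circular
  search region is expanded until an unvisited candidate keeps the local
  turning-angle *difference* within ``theta_max`` (default 20 degrees); a
  half-plane determined by the direction of motion halves the search
  space.  The trace ends when the empty search circle reaches the pot
  circle, or the radius cap is hit.

* **regular morphology** (front view): leaves arch under gravity into
  convex polylines.  Each next keypoint is first held as a *tentative*
  point — the arch-forming candidate of minimal turning angle around the
  chain end — then refined at most once: a nearby candidate lying above
  it that also keeps the chain convex replaces it and is final.  The
  trace ends when no convex continuation remains before the bottom
  reference line (the leaf base) or the radius cap.

Coordinates: x = column, y = row, y grows downward; "above" = smaller y.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from ._geometry import angle_between, arch_test, point_segment_distance
from .sampling import SeedPointSet
from .segmentation import PotCircle, ReferenceLine

__all__ = [
    "TraceParams",
    "SearchDirection",
    "LeafPolyline",
    "PlantSkeleton",
    "find_initial_point",
    "nearest_in_expanding_circle",
    "search_direction",
    "trace_leaf_random",
    "trace_leaf_regular",
    "trace_all",
]


@dataclass(frozen=True)
class TraceParams:
    """Knobs of both tracers.

    ``r0`` and ``theta_max`` are the method's fixed constants; the rest
    are implementation parameters (radius growth/cap, minimum polyline
    length, post-trace consumption corridor).
    """

    r0: float = 5.0
    r_step: float = 5.0
    r_max: float | None = None       # None: set via resolved()
    theta_max: float = 20.0
    min_keypoints: int = 3
    consume_width: float = 12.0
    dir_baseline: float = 20.0       # px, min backward baseline for direction estimates
    halfplane_mode: Literal["axis", "vector"] = "axis"

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.r_step <= 0:
            raise ValueError("r0 and r_step must be positive")
        if self.r_max is not None and self.r_max <= self.r0:
            raise ValueError("r_max must exceed r0")
        if not (0.0 < self.theta_max < 180.0):
            raise ValueError("theta_max must lie in (0, 180)")
        if self.min_keypoints < 3:
            raise ValueError("min_keypoints must be >= 3")

    def resolved(self, image_shape: tuple[int, int] | None = None) -> "TraceParams":
        """Fill ``r_max`` (quarter of the image diagonal) if unset."""
        if self.r_max is not None:
            return self
        if image_shape is None:
            raise ValueError("image_shape needed to resolve r_max")
        h, w = image_shape[:2]
        return replace(self, r_max=float(np.hypot(h, w)) / 4.0)


@dataclass(frozen=True)
class SearchDirection:
    """Axis-aligned half-plane of continued motion."""

    axis: Literal["horizontal", "vertical"]
    sense: int  # +1 increasing coordinate, -1 decreasing

    def __post_init__(self) -> None:
        if self.axis not in ("horizontal", "vertical"):
            raise ValueError("axis must be 'horizontal' or 'vertical'")
        if self.sense not in (-1, 1):
            raise ValueError("sense must be +1 or -1")


@dataclass
class LeafPolyline:
    """Ordered keypoints of one leaf; index 0 is the leaf tip."""

    keypoints: np.ndarray  # (N, 2) float, (x, y)
    leaf_id: int

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.keypoints)


@dataclass
class PlantSkeleton:
    """All midrib polylines of one plant plus its spatial references."""

    leaves: list[LeafPolyline]
    view: Literal["top", "front"]
    pot: PotCircle | None = None
    reference: ReferenceLine | None = None

    @property
    def tips(self) -> np.ndarray:
        return np.array([lf.keypoints[0] for lf in self.leaves], float).reshape(-1, 2)


def _lex_key(points: np.ndarray, idx: np.ndarray, primary: np.ndarray | None = None):
    """Deterministic winner among candidate indices.

    Orders by the primary score, then Euclidean-distance column(s) if
    supplied inside ``primary``, then (y, x).  ``primary`` is a tuple of
    arrays aligned with ``idx``; smaller is better everywhere.
    """
    cols = list(primary) if primary is not None else []
    cols += [points[idx, 1], points[idx, 0]]
    order = np.lexsort(tuple(np.asarray(c, float) for c in reversed(cols)))
    return idx[order[0]]


def find_initial_point(points: SeedPointSet, anchor) -> int | None:
    """Index of the unvisited point farthest from ``anchor`` (leaf tip).

    Ties break toward the smaller (y, x).  Returns None when every point
    has been visited (outer-loop exhaustion).
    """
    idx = points.unvisited_indices
    if len(idx) == 0:
        return None
    anchor = np.asarray(anchor, float)
    d = np.hypot(*(points.points[idx] - anchor).T)
    return int(_lex_key(points.points, idx, primary=(-d,)))


def _in_half_plane(pts: np.ndarray, cur: np.ndarray, prev: np.ndarray, mode: str) -> np.ndarray:
    if mode == "vector":
        return (pts - cur) @ (cur - prev) > 0.0
    sd = search_direction(prev, cur)
    axis = 0 if sd.axis == "horizontal" else 1
    return (pts[:, axis] - cur[axis]) * sd.sense > 0.0


def nearest_in_expanding_circle(
    center,
    points: SeedPointSet,
    params: TraceParams,
    half_plane: tuple[np.ndarray, np.ndarray] | None = None,
) -> int | None:
    """Closest unvisited point found by growing a circular search region.

    The radius starts at ``r0`` and grows by ``r_step`` until at least one
    unvisited point (restricted to the half-plane of motion if
    ``half_plane=(prev, cur)`` is given) lies inside, or the radius passes
    ``r_max``.  Returns the closest such point's index, or None.
    """
    if params.r_max is None:
        raise ValueError("params.r_max is unset; call TraceParams.resolved first")
    center = np.asarray(center, float)
    idx = points.unvisited_indices
    if len(idx) == 0:
        return None
    pts = points.points[idx]
    if half_plane is not None:
        prev, cur = half_plane
        keep = _in_half_plane(pts, np.asarray(cur, float), np.asarray(prev, float), params.halfplane_mode)
        idx, pts = idx[keep], pts[keep]
        if len(idx) == 0:
            return None
    d = np.hypot(*(pts - center).T)
    r = params.r0
    while r <= params.r_max + 1e-9:
        inside = d <= r + 1e-9
        if inside.any():
            return int(_lex_key(points.points, idx[inside], primary=(d[inside],)))
        r += params.r_step
    return None


def search_direction(p1, p2) -> SearchDirection:
    """Axis-aligned direction of motion from p1 to p2.

    The dominant coordinate difference selects the axis (ties go to
    horizontal); the sense is the sign of the motion along that axis.
    Subsequent keypoints are searched strictly beyond the current point
    in that sense.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    dx, dy = p2 - p1
    if dx == 0.0 and dy == 0.0:
        raise ValueError("search_direction undefined for identical points")
    if abs(dx) >= abs(dy):
        return SearchDirection("horizontal", 1 if dx > 0 else -1)
    return SearchDirection("vertical", 1 if dy > 0 else -1)


def _turn(a, b, c) -> float:
    return angle_between(np.asarray(b, float) - a, np.asarray(c, float) - b)


def _back_anchor(pts: np.ndarray, chain: list[int], upto: int, min_len: float) -> np.ndarray:
    """Reference point for the chain direction at ``chain[upto]``: the most
    recent earlier keypoint at least ``min_len`` away.

    Seed points from adjacent grid cells can lie only a couple of pixels
    apart; a direction read off such a micro-segment is numerically
    meaningless, so angles are measured over a baseline of at least
    ``TraceParams.dir_baseline`` (about two sampling-grid cells in the
    default pipeline).
    """
    end = pts[chain[upto]]
    for k in range(upto - 1, -1, -1):
        p = pts[chain[k]]
        if float(np.hypot(*(p - end))) >= min_len:
            return p
    return pts[chain[0]] if upto > 0 else end


def trace_leaf_random(
    points: SeedPointSet,
    start: int,
    pot: PotCircle | None,
    params: TraceParams,
) -> list[int] | None:
    """Random-morphology (top view) tracer; returns accepted point indices
    tip-first, or None when fewer than ``min_keypoints`` were accepted.

    Selection rules per step (circle grown from the last keypoint):
    the 2nd point is simply the closest unvisited; the 3rd minimises the
    turning angle against the first segment; later points minimise the
    *difference* between their turning angle and the previous one.  A
    candidate is accepted only if its criterion value is <= ``theta_max``;
    otherwise the circle keeps expanding.  The trace stops when the empty
    search circle intersects the pot circle or the radius cap is reached.
    Accepted points (including the start) are marked visited.
    """
    if params.r_max is None:
        raise ValueError("params.r_max is unset; call TraceParams.resolved first")
    if points.visited[start]:
        raise ValueError("start point already visited")
    pts = points.points
    chain = [start]
    points.mark_visited(start)

    while True:
        cur = pts[chain[-1]]
        anchor = _back_anchor(pts, chain, len(chain) - 1, params.dir_baseline) if len(chain) >= 2 else cur
        idx = points.unvisited_indices
        if len(idx) and len(chain) >= 2:
            keep = _in_half_plane(pts[idx], cur, anchor, params.halfplane_mode)
            idx = idx[keep]
        d = np.hypot(*(pts[idx] - cur).T) if len(idx) else np.empty(0)

        chosen: int | None = None
        r = params.r0
        while r <= params.r_max + 1e-9:
            inside = idx[d <= r + 1e-9] if len(idx) else idx
            if len(inside):
                di = np.hypot(*(pts[inside] - cur).T)
                if len(chain) == 1:
                    chosen = int(_lex_key(pts, inside, primary=(di,)))
                    break
                if len(chain) == 2:
                    score = np.array(
                        [angle_between(cur - anchor, pts[k] - cur) for k in inside]
                    )
                else:
                    # previous turning angle measured between the smoothed
                    # chain directions at the last two keypoints — comparing
                    # raw segments lets noise ratchet the reference turn up
                    prev = pts[chain[-2]]
                    a2 = _back_anchor(pts, chain, len(chain) - 2, params.dir_baseline)
                    prev_turn = (
                        angle_between(prev - a2, cur - anchor)
                        if not (np.array_equal(a2, prev) or np.array_equal(anchor, cur))
                        else 0.0
                    )
                    score = np.array(
                        [abs(angle_between(cur - anchor, pts[k] - cur) - prev_turn) for k in inside]
                    )
                if score.min() <= params.theta_max + 1e-9:
                    chosen = int(_lex_key(pts, inside, primary=(score, di)))
                    break
            # no acceptable candidate at this radius: if the search circle
            # already reaches the pot, the leaf base has been reached
            if pot is not None and float(np.hypot(*(cur - np.asarray(pot.center)))) <= pot.radius + r:
                break
            r += params.r_step

        if chosen is None:
            break
        points.mark_visited(chosen)
        chain.append(chosen)

    return chain if len(chain) >= params.min_keypoints else None


def trace_leaf_regular(
    points: SeedPointSet,
    start: int,
    params: TraceParams,
    reference: ReferenceLine | None = None,
) -> list[int] | None:
    """Regular-morphology (front view) tracer; returns confirmed point
    indices tip-first, or None when fewer than ``min_keypoints`` survive.

    The 2nd point is the one with the closest row coordinate to the tip
    among the first expanding circle holding >= 2 unvisited points.  Each
    later keypoint is chosen as a tentative point — the candidate forming
    an arch (convex) triple with the chain behind it at minimal turning
    angle, the circle expanding until one exists — and refined at most
    once: a candidate near the tentative point that lies above it and
    stays convex with the confirmed chain replaces it and is final.

    The trace ends when no convex continuation is found before the search
    circle reaches the bottom reference line (the leaf base; analogue of
    the top-view pot-circle termination) or the radius cap is hit.
    """
    if params.r_max is None:
        raise ValueError("params.r_max is unset; call TraceParams.resolved first")
    if points.visited[start]:
        raise ValueError("start point already visited")
    pts = points.points
    points.mark_visited(start)
    p1 = pts[start]

    # --- second point: closest row coordinate within the first circle
    #     containing at least two unvisited points ---------------------
    idx = points.unvisited_indices
    second: int | None = None
    if len(idx):
        d = np.hypot(*(pts[idx] - p1).T)
        r = params.r0
        while r <= params.r_max + 1e-9:
            inside = idx[d <= r + 1e-9]
            if len(inside) >= 2 or (len(inside) >= 1 and r + params.r_step > params.r_max + 1e-9):
                dy = np.abs(pts[inside, 1] - p1[1])
                di = np.hypot(*(pts[inside] - p1).T)
                second = int(_lex_key(pts, inside, primary=(dy, di)))
                break
            if reference is not None and len(inside) == 0 and p1[1] + r >= reference.row:
                break
            r += params.r_step
    if second is None:
        return None
    points.mark_visited(second)
    confirmed = [start, second]

    def _nearby(center: np.ndarray) -> np.ndarray:
        """Unvisited points inside the first non-empty expanding circle.

        Expansion stops early (empty result) when the empty circle
        reaches the bottom reference line: the leaf base was reached.
        """
        idx = points.unvisited_indices
        if len(idx) == 0:
            return idx
        d = np.hypot(*(pts[idx] - center).T)
        r = params.r0
        while r <= params.r_max + 1e-9:
            inside = idx[d <= r + 1e-9]
            if len(inside):
                return inside
            if reference is not None and center[1] + r >= reference.row:
                return idx[:0]
            r += params.r_step
        return idx[:0]

    def _pick_tentative() -> int | None:
        """Arch-forming candidate of minimal turning angle around the
        chain end, with the circle expanded until one is found; None when
        no convex continuation exists before the radius cap or the leaf
        base (reference line) is reached — the leaf is complete."""
        b = pts[confirmed[-1]]
        a = _back_anchor(pts, confirmed, len(confirmed) - 1, params.dir_baseline)
        idx = points.unvisited_indices
        if len(idx) == 0:
            return None
        d = np.hypot(*(pts[idx] - b).T)
        r = params.r0
        while r <= params.r_max + 1e-9:
            inside = idx[d <= r + 1e-9]
            ok = [k for k in inside if arch_test(a, b, pts[k])]
            if ok:
                ok_arr = np.asarray(ok)
                turn = np.array([_turn(a, b, pts[k]) for k in ok_arr])
                di = np.hypot(*(pts[ok_arr] - b).T)
                return int(_lex_key(pts, ok_arr, primary=(turn, di)))
            if reference is not None and b[1] + r >= reference.row:
                return None  # no convex continuation before the leaf base
            r += params.r_step
        return None

    # grow the convex chain through a tentative point, refined at most
    # once: a candidate above the tentative point that stays convex with
    # the confirmed pair replaces it and is final
    while True:
        tem = _pick_tentative()
        if tem is None:
            break
        points.mark_visited(tem)
        b = pts[confirmed[-1]]
        a = _back_anchor(pts, confirmed, len(confirmed) - 1, params.dir_baseline)
        cand_set = _nearby(pts[tem])
        repl = [
            k for k in cand_set
            if pts[k, 1] < pts[tem, 1] and arch_test(a, b, pts[k])
        ]
        if repl:
            repl_arr = np.asarray(repl)
            turn = np.array([_turn(a, b, pts[k]) for k in repl_arr])
            di = np.hypot(*(pts[repl_arr] - pts[tem]).T)
            final = int(_lex_key(pts, repl_arr, primary=(turn, di)))
            points.mark_visited(final)
            # tentative point is discarded (stays retired)
        else:
            final = tem
        confirmed.append(final)

    return confirmed if len(confirmed) >= params.min_keypoints else None


def _extend_to_base(
    poly: np.ndarray,
    view: str,
    pot: PotCircle | None,
    reference: ReferenceLine | None,
) -> np.ndarray:
    """Polyline plus a virtual continuation from its last keypoint to the
    leaf base (the reference row in front view, the pot rim in top view).

    The trace terminates when its empty search circle reaches the pot /
    reference line, so the leaf's physical base section may hold residual
    seed points beyond the last keypoint; the consumption corridor covers
    it by extrapolating the final direction.
    """
    if len(poly) < 2:
        return poly
    end = poly[-1]
    d = end - poly[-2]
    norm = float(np.hypot(*d))
    if norm == 0.0:
        return poly
    d = d / norm
    t = None
    if view == "front" and reference is not None and d[1] > 1e-6 and end[1] < reference.row:
        t = (reference.row - end[1]) / d[1]
    elif view == "top" and pot is not None:
        to_center = np.asarray(pot.center) - end
        dist = float(np.hypot(*to_center))
        if dist > pot.radius and float(to_center @ d) > 0.5 * dist:  # heading potward
            t = dist - pot.radius
    if t is None or t <= 0:
        return poly
    return np.vstack([poly, end + t * d])


def _consume_corridor(points: SeedPointSet, polyline: np.ndarray, width: float) -> None:
    """Retire unvisited points within ``width`` px of the polyline."""
    idx = points.unvisited_indices
    if len(idx) == 0 or len(polyline) < 2:
        return
    dmin = np.full(len(idx), np.inf)
    for a, b in zip(polyline[:-1], polyline[1:]):
        dmin = np.minimum(dmin, point_segment_distance(points.points[idx], a, b))
    points.visited[idx[dmin <= width]] = True


def trace_all(
    points: SeedPointSet,
    view: Literal["top", "front"],
    pot: PotCircle | None = None,
    reference: ReferenceLine | None = None,
    params: TraceParams | None = None,
    anchor=None,
) -> PlantSkeleton:
    """Trace every leaf: repeatedly start from the farthest unvisited
    point and run the view-appropriate tracer.

    ``anchor`` is the tip-selection reference: the pot centre in top view
    (default), or a leaf-base point in front view (defaults to the mean x
    of the seed points on the reference row).  After each accepted leaf a
    corridor of ``consume_width`` around the polyline is retired so
    leftovers cannot seed spurious leaves; discarded traces also retire
    their points.
    """
    if params is None:
        params = TraceParams()
    if params.r_max is None:
        pts = points.points
        if len(pts):
            diag = float(np.hypot(np.ptp(pts[:, 0]), np.ptp(pts[:, 1])))
            params = replace(params, r_max=max(diag, 4.0 * params.r0))
        else:
            params = replace(params, r_max=4.0 * params.r0)
    if anchor is None:
        if view == "top":
            if pot is None:
                raise ValueError("top view needs a pot circle or an explicit anchor")
            anchor = pot.center
        else:
            if len(points) == 0:
                anchor = (0.0, 0.0)
            else:
                row = reference.row if reference is not None else float(points.points[:, 1].max())
                anchor = (float(points.points[:, 0].mean()), float(row))

    leaves: list[LeafPolyline] = []
    leaf_id = 1
    while True:
        idx = points.unvisited_indices
        if view == "top" and pot is not None and len(idx):
            idx = idx[~pot.contains(points.points[idx])]
        if view == "front" and reference is not None and len(idx):
            idx = idx[points.points[idx, 1] < reference.row]
        if len(idx) == 0:
            break
        sub_d = np.hypot(*(points.points[idx] - np.asarray(anchor, float)).T)
        tip = int(_lex_key(points.points, idx, primary=(-sub_d,)))
        if view == "top":
            chain = trace_leaf_random(points, tip, pot, params)
        else:
            chain = trace_leaf_regular(points, tip, params, reference=reference)
        if chain is not None:
            poly = points.points[chain].copy()
            leaves.append(LeafPolyline(keypoints=poly, leaf_id=leaf_id))
            leaf_id += 1
            corridor = _extend_to_base(poly, view, pot, reference)
            _consume_corridor(points, corridor, params.consume_width)

    return PlantSkeleton(leaves=leaves, view=view, pot=pot, reference=reference)
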