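"""Brute-force reference tracers used as independent oracles.

These re-implement the keypoint-connection selection rules with plain
Python loops and exhaustive scans — no arrays, no incremental radius
bookkeeping, no shared helpers with the package implementation.  Every
radius step re-examines every point from scratch; candidate winners are
found with ``min`` over explicit tie-break tuples (criterion value,
distance, y, x).  The production tracers must match these outputs
exactly on small point sets.
"""

from __future__ import annotations

import math


def _dist(p, q) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def _angle(u, v) -> float:
    """Angle between vectors in degrees, [0, 180]."""
    nu = math.hypot(*u)
    nv = math.hypot(*v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero vector")
    c = (u[0] * v[0] + u[1] * v[1]) / (nu * nv)
    c = min(1.0, max(-1.0, c))
    return math.degrees(math.acos(c))


def _arch(p0, p1, p2, straight_tol: float = 20.0) -> bool:
    """Middle vertex on/above the chord, or triple within ``straight_tol``
    degrees of collinear (mirrors the package's arch test semantics)."""
    dx = p2[0] - p0[0]
    cross = dx * (p1[1] - p0[1]) - (p2[1] - p0[1]) * (p1[0] - p0[0])
    if dx != 0.0 and cross * (1.0 if dx > 0 else -1.0) <= 0.0:
        return True
    u = (p1[0] - p0[0], p1[1] - p0[1])
    v = (p2[0] - p1[0], p2[1] - p1[1])
    if (u[0] == 0 and u[1] == 0) or (v[0] == 0 and v[1] == 0):
        return True
    return _angle(u, v) <= straight_tol


def _back_anchor(pts, chain, upto, min_len):
    end = pts[chain[upto]]
    for k in range(upto - 1, -1, -1):
        if _dist(pts[chain[k]], end) >= min_len:
            return pts[chain[k]]
    return pts[chain[0]] if upto > 0 else end


def _half_plane_ok(cand, cur, prev, mode) -> bool:
    if mode == "vector":
        return ((cand[0] - cur[0]) * (cur[0] - prev[0])
                + (cand[1] - cur[1]) * (cur[1] - prev[1])) > 0.0
    dx = cur[0] - prev[0]
    dy = cur[1] - prev[1]
    if abs(dx) >= abs(dy):
        sense = 1 if dx > 0 else -1
        return (cand[0] - cur[0]) * sense > 0.0
    sense = 1 if dy > 0 else -1
    return (cand[1] - cur[1]) * sense > 0.0


def _radii(r0, r_step, r_max):
    r = r0
    while r <= r_max + 1e-9:
        yield r
        r += r_step


def reference_trace_random(pts, visited, start, pot, params) -> list[int] | None:
    """Plain-loop random-morphology tracer.

    ``pts`` is a list of (x, y); ``visited`` a mutable list of booleans
    (updated in place, matching the production visited semantics).
    ``pot`` is ((cx, cy), radius) or None.  ``params`` needs r0, r_step,
    r_max, theta_max, min_keypoints, dir_baseline, halfplane_mode.
    """
    chain = [start]
    visited[start] = True
    while True:
        cur = pts[chain[-1]]
        if len(chain) >= 2:
            anchor = _back_anchor(pts, chain, len(chain) - 1, params.dir_baseline)
        else:
            anchor = cur
        cands = []
        for k in range(len(pts)):
            if visited[k]:
                continue
            if len(chain) >= 2 and not _half_plane_ok(pts[k], cur, anchor, params.halfplane_mode):
                continue
            cands.append(k)

        chosen = None
        for r in _radii(params.r0, params.r_step, params.r_max):
            inside = [k for k in cands if _dist(pts[k], cur) <= r + 1e-9]
            if inside:
                if len(chain) == 1:
                    chosen = min(
                        inside, key=lambda k: (_dist(pts[k], cur), pts[k][1], pts[k][0])
                    )
                    break
                if len(chain) == 2:
                    def crit(k):
                        return _angle(
                            (cur[0] - anchor[0], cur[1] - anchor[1]),
                            (pts[k][0] - cur[0], pts[k][1] - cur[1]),
                        )
                else:
                    prev = pts[chain[-2]]
                    a2 = _back_anchor(pts, chain, len(chain) - 2, params.dir_baseline)
                    if a2 == prev or anchor == cur:
                        prev_turn = 0.0
                    else:
                        prev_turn = _angle(
                            (prev[0] - a2[0], prev[1] - a2[1]),
                            (cur[0] - anchor[0], cur[1] - anchor[1]),
                        )

                    def crit(k, prev_turn=prev_turn):
                        return abs(
                            _angle(
                                (cur[0] - anchor[0], cur[1] - anchor[1]),
                                (pts[k][0] - cur[0], pts[k][1] - cur[1]),
                            )
                            - prev_turn
                        )

                scored = [(crit(k), _dist(pts[k], cur), pts[k][1], pts[k][0], k) for k in inside]
                best = min(scored)
                if best[0] <= params.theta_max + 1e-9:
                    chosen = best[4]
                    break
            if pot is not None and _dist(cur, pot[0]) <= pot[1] + r:
                break
        if chosen is None:
            break
        visited[chosen] = True
        chain.append(chosen)
    return chain if len(chain) >= params.min_keypoints else None


def reference_trace_regular(pts, visited, start, params, reference_row=None) -> list[int] | None:
    """Plain-loop regular-morphology (convexity / curvature-minimising)
    tracer with the one-shot tentative-replacement rule."""
    visited[start] = True
    p1 = pts[start]

    second = None
    for r in _radii(params.r0, params.r_step, params.r_max):
        inside = [
            k for k in range(len(pts)) if not visited[k] and _dist(pts[k], p1) <= r + 1e-9
        ]
        if len(inside) >= 2 or (len(inside) >= 1 and r + params.r_step > params.r_max + 1e-9):
            second = min(
                inside,
                key=lambda k: (abs(pts[k][1] - p1[1]), _dist(pts[k], p1), pts[k][1], pts[k][0]),
            )
            break
        if reference_row is not None and not inside and p1[1] + r >= reference_row:
            break
    if second is None:
        return None
    visited[second] = True
    confirmed = [start, second]

    def nearby(center):
        for r in _radii(params.r0, params.r_step, params.r_max):
            inside = [
                k for k in range(len(pts))
                if not visited[k] and _dist(pts[k], center) <= r + 1e-9
            ]
            if inside:
                return inside
            if reference_row is not None and center[1] + r >= reference_row:
                return []
        return []

    def pick_tentative():
        b = pts[confirmed[-1]]
        a = _back_anchor(pts, confirmed, len(confirmed) - 1, params.dir_baseline)
        for r in _radii(params.r0, params.r_step, params.r_max):
            ok = [
                k for k in range(len(pts))
                if not visited[k]
                and _dist(pts[k], b) <= r + 1e-9
                and _arch(a, b, pts[k])
            ]
            if ok:
                return min(
                    ok,
                    key=lambda k: (
                        _angle((b[0] - a[0], b[1] - a[1]), (pts[k][0] - b[0], pts[k][1] - b[1])),
                        _dist(pts[k], b),
                        pts[k][1],
                        pts[k][0],
                    ),
                )
            if reference_row is not None and b[1] + r >= reference_row:
                return None
        return None

    while True:
        tem = pick_tentative()
        if tem is None:
            break
        visited[tem] = True
        b = pts[confirmed[-1]]
        a = _back_anchor(pts, confirmed, len(confirmed) - 1, params.dir_baseline)
        repl = [
            k for k in nearby(pts[tem])
            if pts[k][1] < pts[tem][1] and _arch(a, b, pts[k])
        ]
        if repl:
            final = min(
                repl,
                key=lambda k: (
                    _angle((b[0] - a[0], b[1] - a[1]), (pts[k][0] - b[0], pts[k][1] - b[1])),
                    _dist(pts[k], pts[tem]),
                    pts[k][1],
                    pts[k][0],
                ),
            )
            visited[final] = True
        else:
            final = tem
        confirmed.append(final)
    return confirmed if len(confirmed) >= params.min_keypoints else None
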