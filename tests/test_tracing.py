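"""Keypoint-connection tracers: selection rules, termination, invariants."""

import math

import numpy as np
import pytest

from leafskel._geometry import angle_between, arch_test
from leafskel.sampling import SeedPointSet
from leafskel.segmentation import PotCircle, ReferenceLine
from leafskel.tracing import (
    TraceParams,
    find_initial_point,
    nearest_in_expanding_circle,
    search_direction,
    trace_all,
    trace_leaf_random,
    trace_leaf_regular,
)

from reference_tracer import (
    _angle as ref_angle,
    _back_anchor as ref_back_anchor,
    reference_trace_random,
    reference_trace_regular,
)

PARAMS = TraceParams(r_max=150.0)


def _pointset(pts):
    return SeedPointSet(np.asarray(pts, float), rng_seed=0)


class TestAngleBetween:
    @pytest.mark.parametrize(
        "u,v,expected",
        [((1, 0), (1, 0), 0.0), ((1, 0), (0, 1), 90.0), ((1, 0), (-1, 0), 180.0)],
    )
    def test_values(self, u, v, expected):
        assert angle_between(u, v) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            angle_between((0, 0), (1, 0))


class TestFindInitialPoint:
    def test_farthest_point_wins(self):
        pts = _pointset([(0, 0), (10, 0)])
        assert find_initial_point(pts, (0, 0)) == 1

    def test_distance_tie_breaks_by_row_then_column(self):
        pts = _pointset([(0, 10), (10, 0)])  # both at distance 10 from origin
        assert find_initial_point(pts, (0, 0)) == 1  # smaller y wins

    def test_exhaustion_returns_none(self):
        pts = _pointset([(1, 1)])
        pts.visited[:] = True
        assert find_initial_point(pts, (0, 0)) is None


class TestExpandingCircle:
    def test_point_within_initial_radius(self):
        pts = _pointset([(3, 0)])
        assert nearest_in_expanding_circle((0, 0), pts, PARAMS) == 0

    def test_closest_of_several_selected(self):
        pts = _pointset([(4.5, 0), (0, 4.0)])
        assert nearest_in_expanding_circle((0, 0), pts, PARAMS) == 1

    def test_all_beyond_radius_cap_gives_none(self):
        pts = _pointset([(500, 500)])
        assert nearest_in_expanding_circle((0, 0), pts, PARAMS) is None


class TestSearchDirection:
    def test_leftward_motion(self):
        sd = search_direction((10, 0), (5, 0))
        assert (sd.axis, sd.sense) == ("horizontal", -1)

    def test_downward_motion_mirrors_horizontal_rule(self):
        sd = search_direction((0, 0), (0, 8))
        assert (sd.axis, sd.sense) == ("vertical", 1)

    def test_diagonal_tie_prefers_horizontal(self):
        sd = search_direction((0, 0), (5, 5))
        assert sd.axis == "horizontal"

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            search_direction((1, 2), (1, 2))


class TestTraceLeafRandom:
    def test_collinear_points_connect_in_order(self):
        pts = _pointset([(4 * i, 0) for i in range(10)])
        chain = trace_leaf_random(pts, 0, None, PARAMS)
        assert chain == list(range(10))

    def test_smaller_turn_candidate_wins(self):
        a10 = math.radians(10)
        a25 = math.radians(-25)
        pts = _pointset(
            [
                (0, 0),
                (20, 0),
                (20 + 10 * math.cos(a10), 10 * math.sin(a10)),
                (20 + 10 * math.cos(a25), 10 * math.sin(a25)),
            ]
        )
        chain = trace_leaf_random(pts, 0, None, PARAMS)
        assert chain[:3] == [0, 1, 2]

    def test_only_sharp_turn_available_ends_trace(self):
        a30 = math.radians(30)
        pts = _pointset([(0, 0), (20, 0), (20 + 10 * math.cos(a30), 10 * math.sin(a30))])
        params = TraceParams(r_max=40.0)
        assert trace_leaf_random(pts, 0, None, params) is None  # 2 < min_keypoints
        assert pts.visited[0] and pts.visited[1] and not pts.visited[2]

    def test_empty_circle_at_pot_terminates(self):
        pts = _pointset([(100, 0), (80, 0), (60, 0), (40, 0)])
        pot = PotCircle(center=(0.0, 0.0), radius=30.0)
        chain = trace_leaf_random(pts, 0, pot, TraceParams(r_max=300.0))
        assert chain == [0, 1, 2, 3]


class TestTraceLeafRegular:
    def test_vertical_points_connect_sequentially(self):
        pts = _pointset([(50, 10 + 20 * i) for i in range(6)])
        chain = trace_leaf_regular(pts, 0, PARAMS)
        assert chain == list(range(6))

    def test_arch_points_recovered_in_order(self):
        xs = np.linspace(20, 100, 10)
        rows = 0.02 * (xs - 60) ** 2 + 40.0
        pts = _pointset(np.column_stack([xs, rows]))
        start = 0  # x = 20 end, farthest from a base at (60, 140)
        chain = trace_leaf_regular(pts, start, PARAMS)
        assert chain is not None
        assert [pts.points[k, 0] for k in chain] == sorted(pts.points[chain, 0])
        for i in range(len(chain) - 2):
            assert arch_test(*pts.points[chain[i:i + 3]])

    def test_higher_convex_candidate_replaces_tentative(self):
        # confirmed pair moving right; tentative at row 100; a convex
        # candidate above it (row 90) must replace it in the chain
        pts = _pointset([(0, 110), (20, 104), (40, 100), (42, 90)])
        chain = trace_leaf_regular(pts, 0, PARAMS)
        assert chain is not None
        assert 3 in chain and 2 not in chain

    def test_matches_exhaustive_reference_on_arch(self):
        xs = np.linspace(20, 100, 12)
        rows = 0.015 * (xs - 65) ** 2 + 35.0
        pts = np.column_stack([xs, rows])
        sp = _pointset(pts)
        got = trace_leaf_regular(sp, 0, PARAMS)
        vis = [False] * len(pts)
        want = reference_trace_regular([tuple(p) for p in pts], vis, 0, PARAMS)
        assert got == want


class TestTraceAll:
    def test_empty_point_set_gives_zero_leaves(self):
        skel = trace_all(_pointset(np.empty((0, 2))), "top", anchor=(0, 0))
        assert skel.leaves == []

    def test_two_disjoint_chains_give_two_leaves(self):
        chain_a = [(4 * i, 0) for i in range(10)]
        chain_b = [(4 * i, 200) for i in range(10)]
        pts = _pointset(chain_a + chain_b)
        params = TraceParams(r_max=60.0)
        skel = trace_all(pts, "top", params=params, anchor=(0, 100))
        assert len(skel.leaves) == 2
        tips = {tuple(lf.keypoints[0]) for lf in skel.leaves}
        assert tips == {(36.0, 0.0), (36.0, 200.0)}

    def test_synthetic_plant_recovers_leaf_count(self, top_plant, top_result):
        assert len(top_result.skeleton.leaves) == top_plant.gt_count

    def test_leaf_vertex_sets_disjoint(self, top_result, front_result):
        for res in (top_result, front_result):
            seen = set()
            for lf in res.skeleton.leaves:
                for xy in map(tuple, lf.keypoints):
                    assert xy not in seen
                    seen.add(xy)


class TestInvariants:
    def test_random_tracer_angle_differences_bounded(self, top_result):
        """Every accepted step satisfies the angle-difference criterion,
        recomputed independently with the reference implementation's
        helpers."""
        params = TraceParams(r_max=1.0e9, dir_baseline=2 * 640 / 40)
        for lf in top_result.skeleton.leaves:
            kp = [tuple(p) for p in lf.keypoints]
            chain = list(range(len(kp)))
            for i in range(3, len(kp)):
                cur = kp[i - 1]
                anchor = ref_back_anchor(kp, chain, i - 1, params.dir_baseline)
                prev = kp[i - 2]
                a2 = ref_back_anchor(kp, chain, i - 2, params.dir_baseline)
                if a2 == prev or anchor == cur:
                    prev_turn = 0.0
                else:
                    prev_turn = ref_angle(
                        (prev[0] - a2[0], prev[1] - a2[1]),
                        (cur[0] - anchor[0], cur[1] - anchor[1]),
                    )
                turn = ref_angle(
                    (cur[0] - anchor[0], cur[1] - anchor[1]),
                    (kp[i][0] - cur[0], kp[i][1] - cur[1]),
                )
                assert abs(turn - prev_turn) <= params.theta_max + 1e-6

    def test_regular_tracer_output_passes_arch_test(self, front_result):
        """Each confirmed keypoint forms an arch (convex) triple with the
        chain behind it, measured over the direction baseline exactly as
        the tracer enforces it."""
        baseline = 2 * len(front_result.leaf_mask) / 40
        for lf in front_result.skeleton.leaves:
            kp = [tuple(p) for p in lf.keypoints]
            chain = list(range(len(kp)))
            for i in range(1, len(kp) - 1):
                a = ref_back_anchor(kp, chain, i, baseline)
                assert arch_test(a, kp[i], kp[i + 1])

    def test_tracers_match_reference_on_random_sets(self):
        params = TraceParams(r_max=150.0)
        for seed in range(50):
            rg = np.random.default_rng(seed)
            pts = np.unique(np.round(rg.uniform(0, 100, (int(rg.integers(3, 13)), 2)), 1), axis=0)
            if len(pts) < 3:
                continue
            d = np.hypot(*(pts - 50).T)
            start = int(np.lexsort((pts[:, 0], pts[:, 1], -d))[0])
            pot = PotCircle(center=(50.0, 50.0), radius=10.0) if seed % 2 else None
            sp = _pointset(pts)
            mine = trace_leaf_random(sp, start, pot, params)
            vis = [False] * len(pts)
            ref = reference_trace_random(
                [tuple(p) for p in pts], vis, start,
                (tuple(pot.center), pot.radius) if pot else None, params,
            )
            assert mine == ref

    def test_tracers_always_halt_and_mark_visited(self, rng):
        pts = np.unique(np.round(rng.uniform(0, 60, (40, 2)), 1), axis=0)
        sp = _pointset(pts)
        skel = trace_all(sp, "front", reference=ReferenceLine(row=70), params=TraceParams(r_max=90.0), anchor=(30, 70))
        total = sum(len(lf.keypoints) for lf in skel.leaves)
        assert total <= len(pts)
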