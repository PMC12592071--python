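"""Geometric phenotypes: crown width, consistencies, ring partition."""

import numpy as np
import pytest

from leafskel.phenotypes import (
    crown_width,
    distribution_consistency,
    gaussian_weights,
    height_consistency,
    leaf_count,
    length_consistency,
    phenotype_report,
    relative_crown_width,
)
from leafskel.segmentation import PotCircle, ReferenceLine
from leafskel.tracing import LeafPolyline, PlantSkeleton


def _skeleton(polys, view="top", pot=None, reference=None):
    leaves = [
        LeafPolyline(keypoints=np.asarray(p, float), leaf_id=i + 1) for i, p in enumerate(polys)
    ]
    return PlantSkeleton(leaves=leaves, view=view, pot=pot, reference=reference)


def _radial_skeleton(k, pot_radius=20.0, tip_radius=100.0, n_pts=6, rotate=0.0):
    """k straight leaves radiating at exact equal angular spacing."""
    polys = []
    for j in range(k):
        ang = np.radians(360.0 * j / k + rotate)
        rr = np.linspace(tip_radius, pot_radius + 2.0, n_pts)  # tip first
        polys.append(np.column_stack([rr * np.cos(ang), rr * np.sin(ang)]))
    return _skeleton(polys, pot=PotCircle(center=(0.0, 0.0), radius=pot_radius))


class TestCounts:
    def test_leaf_count(self):
        skel = _skeleton([[(0, 0), (1, 0), (2, 0)]] * 3)
        assert leaf_count(skel) == 3

    def test_empty_skeleton(self):
        assert leaf_count(_skeleton([])) == 0

    def test_end_to_end_count(self, top_plant, top_result):
        assert top_result.report.leaf_count == top_plant.gt_count


class TestCrownWidth:
    def test_max_pairwise_tip_distance(self):
        skel = _skeleton([[(0, 0), (1, 1), (2, 2)], [(200, 0), (199, 1), (198, 2)]])
        cw = crown_width(skel)
        assert cw == pytest.approx(200.0)
        pot = PotCircle(center=(100.0, 0.0), radius=50.0)
        assert relative_crown_width(cw, pot) == pytest.approx(2.0)

    def test_coincident_tips_give_zero(self):
        skel = _skeleton([[(5, 5), (6, 6), (7, 7)], [(5, 5), (4, 6), (3, 7)]])
        assert crown_width(skel) == 0.0

    def test_diametrically_opposed_rim_tips_give_unit_ratio(self):
        pot = PotCircle(center=(0.0, 0.0), radius=40.0)
        skel = _skeleton([[(-40, 0), (-30, 0), (-20, 0)], [(40, 0), (30, 0), (20, 0)]])
        assert relative_crown_width(crown_width(skel), pot) == pytest.approx(1.0)

    def test_single_leaf_is_undefined(self):
        with pytest.raises(ValueError):
            crown_width(_skeleton([[(0, 0), (1, 0), (2, 0)]]))


class TestLengthConsistency:
    def test_identical_lengths_give_zero(self):
        skel = _skeleton([[(0, 0), (5, 0)], [(0, 10), (5, 10)]])
        assert length_consistency(skel) == 0.0

    def test_population_variance_convention(self):
        skel = _skeleton([[(0, 0), (3, 0)], [(0, 10), (5, 10)]])  # lengths 3 and 5
        assert length_consistency(skel) == pytest.approx(1.0)

    def test_single_leaf_gives_zero(self):
        assert length_consistency(_skeleton([[(0, 0), (7, 0)]])) == 0.0


class TestGaussianWeights:
    def test_single_ring(self):
        assert gaussian_weights(1, 2.0) == pytest.approx([1.0])

    def test_huge_sigma_is_uniform(self):
        assert gaussian_weights(5, 1e6) == pytest.approx([0.2] * 5)

    @pytest.mark.parametrize("n", [1, 2, 5, 9, 100, 1000])
    def test_sum_one_and_mid_argmax(self, n):
        w = gaussian_weights(n, n / 4.0)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.argmax(w) + 1 == round(n / 2) or (n == 1 and np.argmax(w) == 0)


class TestDistributionConsistency:
    def test_equal_radial_spacing_gives_zero(self):
        skel = _radial_skeleton(6)
        val = distribution_consistency(skel, skel.pot)
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_single_ring_hand_geometry(self):
        """Three radial leaves at 0, 90 and 180 degrees crossing one ring:
        arcs R*pi/2, R*pi/2 and R*pi, variance computed by hand."""
        pot = PotCircle(center=(0.0, 0.0), radius=20.0)
        polys = []
        for ang in (0.0, 90.0, 180.0):
            a = np.radians(ang)
            rr = np.linspace(100.0, 22.0, 8)
            polys.append(np.column_stack([rr * np.cos(a), rr * np.sin(a)]))
        skel = _skeleton(polys, pot=pot)
        # crown radius 100, one ring at r = 20 + (100-20)/2 = 60
        R = 60.0
        arcs = np.array([R * np.pi / 2, R * np.pi / 2, R * np.pi])
        want = float(np.var(arcs))
        got = distribution_consistency(skel, pot, n_rings=1)
        assert got == pytest.approx(want, rel=1e-9)

    def test_empty_rings_skipped_and_weights_renormalized(self):
        """Leaves spanning only the outer half: inner rings have no
        intersections and the weighted average uses the outer rings only."""
        pot = PotCircle(center=(0.0, 0.0), radius=20.0)
        polys = []
        for ang in (0.0, 120.0, 250.0):
            a = np.radians(ang)
            rr = np.linspace(100.0, 65.0, 5)  # outer-third segments only
            polys.append(np.column_stack([rr * np.cos(a), rr * np.sin(a)]))
        skel = _skeleton(polys, pot=pot)
        val, part = distribution_consistency(skel, pot, n_rings=3, return_partition=True)
        populated = [arcs for arcs in part.arcs_per_ring if arcs]
        assert len(populated) == 1
        assert sum(part.weights) == pytest.approx(1.0)
        assert val == pytest.approx(np.var(populated[0]))

    def test_rotation_invariance(self):
        a = distribution_consistency(_radial_skeleton(5, rotate=0.0), PotCircle((0.0, 0.0), 20.0))
        b = distribution_consistency(_radial_skeleton(5, rotate=17.0), PotCircle((0.0, 0.0), 20.0))
        assert a == pytest.approx(b, abs=1e-6)


class TestHeightConsistency:
    def test_equal_mean_heights_give_zero(self):
        ref = ReferenceLine(row=100)
        skel = _skeleton([[(0, 40), (5, 60)], [(20, 30), (25, 70)]], view="front")
        assert height_consistency(skel, ref) == 0.0  # both means 50 -> height 50

    def test_population_variance_of_means(self):
        ref = ReferenceLine(row=100)
        skel = _skeleton([[(0, 90), (5, 90)], [(20, 80), (25, 80)]], view="front")
        assert height_consistency(skel, ref) == pytest.approx(25.0)

    def test_keypoints_below_line_contribute_negative_heights(self):
        ref = ReferenceLine(row=100)
        skel = _skeleton([[(0, 110), (5, 110)]], view="front")  # height -10
        assert height_consistency(skel, ref) == 0.0
        means = np.mean(ref.row - skel.leaves[0].keypoints[:, 1])
        assert means == -10.0


class TestInvarianceProperties:
    def _report_numbers(self, skel):
        rep = phenotype_report(skel)
        return rep

    def test_translation_invariance_exact(self):
        skel = _radial_skeleton(6)
        shifted = _skeleton(
            [lf.keypoints + np.array([37.0, -12.0]) for lf in skel.leaves],
            pot=PotCircle(center=(37.0, -12.0), radius=skel.pot.radius),
        )
        a, b = phenotype_report(skel), phenotype_report(shifted)
        assert a.crown_width == pytest.approx(b.crown_width, abs=1e-9)
        assert a.length_consistency == pytest.approx(b.length_consistency, abs=1e-9)
        assert a.distribution_consistency == pytest.approx(b.distribution_consistency, abs=1e-9)

    def test_scale_covariance(self):
        s = 2.5
        skel = _radial_skeleton(5, rotate=13.0)
        scaled = _skeleton(
            [lf.keypoints * s for lf in skel.leaves],
            pot=PotCircle(center=(0.0, 0.0), radius=skel.pot.radius * s),
        )
        a, b = phenotype_report(skel), phenotype_report(scaled)
        assert b.crown_width == pytest.approx(s * a.crown_width, rel=1e-9)
        assert b.relative_crown_width == pytest.approx(a.relative_crown_width, rel=1e-9)
        assert b.length_consistency == pytest.approx(s**2 * a.length_consistency, abs=1e-9)
        assert b.distribution_consistency == pytest.approx(
            s**2 * a.distribution_consistency, abs=1e-6
        )

    def test_height_scale_covariance(self):
        ref = ReferenceLine(row=100)
        skel = _skeleton([[(0, 90), (5, 88)], [(20, 60), (25, 40)]], view="front")
        s = 3.0
        scaled = _skeleton(
            [lf.keypoints * s for lf in skel.leaves], view="front"
        )
        a = height_consistency(skel, ref)
        b = height_consistency(scaled, ReferenceLine(row=300))
        assert b == pytest.approx(s**2 * a, rel=1e-12)
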