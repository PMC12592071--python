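"""Geometric phenotypes computed from a traced plant skeleton.

Top view: leaf count, crown width (max pairwise tip distance), relative
crown width (crown width / pot diameter), leaf length consistency
(variance of per-leaf skeleton length) and leaf distribution consistency
(Gaussian-weighted variance of inter-leaf arc lengths on concentric
rings between the pot circle and the crown circle).  Front view: leaf
height consistency (variance of each leaf's mean keypoint height above
the bottom reference line).

All variances are population (divide-by-n) variances; consistency values
are therefore in px² and *smaller is more consistent*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import circle_segment_intersections, polyline_length
from .segmentation import PotCircle, ReferenceLine
from .tracing import PlantSkeleton

__all__ = [
    "PhenotypeReport",
    "RingPartition",
    "leaf_count",
    "crown_width",
    "relative_crown_width",
    "length_consistency",
    "gaussian_weights",
    "distribution_consistency",
    "height_consistency",
    "phenotype_report",
]


@dataclass
class PhenotypeReport:
    """One plant's phenotypes; view-inapplicable fields stay None."""

    view: str
    leaf_count: int
    crown_width: float | None = None            # px, top view
    relative_crown_width: float | None = None   # dimensionless, top view
    length_consistency: float | None = None     # px^2, top view
    distribution_consistency: float | None = None  # px^2, top view
    height_consistency: float | None = None     # px^2, front view

    def to_dict(self) -> dict:
        return {
            "view": self.view,
            "leaf_count": self.leaf_count,
            "crown_width": self.crown_width,
            "relative_crown_width": self.relative_crown_width,
            "length_consistency": self.length_consistency,
            "distribution_consistency": self.distribution_consistency,
            "height_consistency": self.height_consistency,
        }


@dataclass
class RingPartition:
    """Diagnostics of the concentric-ring construction."""

    ring_radii: list[float]
    arcs_per_ring: list[list[float]] = field(default_factory=list)
    weights: list[float] = field(default_factory=list)


def _pop_var(values) -> float:
    v = np.asarray(values, float)
    return float(np.var(v)) if len(v) else 0.0


def leaf_count(skeleton: PlantSkeleton) -> int:
    """Number of traced midrib polylines."""
    return len(skeleton.leaves)


def crown_width(skeleton: PlantSkeleton) -> float:
    """Maximum pairwise Euclidean distance between leaf tips, px."""
    tips = skeleton.tips
    if len(tips) < 2:
        raise ValueError("crown width needs at least two leaves")
    diff = tips[:, None, :] - tips[None, :, :]
    return float(np.hypot(diff[..., 0], diff[..., 1]).max())


def relative_crown_width(cw: float, pot: PotCircle) -> float:
    """Crown width divided by the pot diameter (scale-robust)."""
    return cw / (2.0 * pot.radius)


def length_consistency(skeleton: PlantSkeleton) -> float:
    """Population variance of per-leaf skeleton length, px^2."""
    if not skeleton.leaves:
        raise ValueError("length consistency needs at least one leaf")
    return _pop_var([polyline_length(lf.keypoints) for lf in skeleton.leaves])


def gaussian_weights(N: int, sigma: float) -> np.ndarray:
    """Softmax of -(j - N/2)^2 / (2 sigma^2) for j = 1..N.

    Sums to one; maximal at the ring index nearest N/2, emphasising
    mid-radius rings where inter-leaf spacing best reflects uniformity.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    j = np.arange(1, N + 1, dtype=float)
    logit = -((j - N / 2.0) ** 2) / (2.0 * sigma**2)
    logit -= logit.max()
    w = np.exp(logit)
    return w / w.sum()


def distribution_consistency(
    skeleton: PlantSkeleton,
    pot: PotCircle,
    n_rings: int = 9,
    sigma: float | None = None,
    return_partition: bool = False,
):
    """Gaussian-weighted variance of inter-leaf arc lengths on concentric
    rings, px^2.

    The crown circle has the crown width as diameter and the pot centre
    as centre.  ``n_rings`` circles are placed at equal radial increments
    strictly between the pot and crown circles; each ring is intersected
    with all midrib segments, the intersection angles sorted, and the
    arcs between consecutive intersections measured.  Rings with fewer
    than two intersections are skipped and the Gaussian weights are
    renormalised over the remaining rings.
    """
    if len(skeleton.leaves) < 2:
        raise ValueError("distribution consistency needs at least two leaves")
    r_crown = crown_width(skeleton) / 2.0
    if r_crown <= pot.radius:
        raise ValueError("crown radius must exceed the pot radius")
    if sigma is None:
        sigma = n_rings / 4.0
    cx, cy = pot.center
    radii = [
        pot.radius + (r_crown - pot.radius) * j / (n_rings + 1.0)
        for j in range(1, n_rings + 1)
    ]
    weights = gaussian_weights(n_rings, sigma)
    part = RingPartition(ring_radii=radii)
    ring_vars: list[float] = []
    ring_w: list[float] = []
    for j, R in enumerate(radii):
        angles: list[float] = []
        for leaf in skeleton.leaves:
            kp = leaf.keypoints
            for a, b in zip(kp[:-1], kp[1:]):
                for px, py in circle_segment_intersections((cx, cy), R, a, b):
                    angles.append(float(np.arctan2(py - cy, px - cx)))
        angles = sorted(angles)
        # merge duplicates (tangency / shared vertices) within 1e-9 rad
        merged: list[float] = []
        for t in angles:
            if not merged or t - merged[-1] > 1e-9:
                merged.append(t)
        if len(merged) >= 2 and (merged[0] + 2 * np.pi) - merged[-1] <= 1e-9:
            merged.pop()
        if len(merged) < 2:
            part.arcs_per_ring.append([])
            continue
        gaps = np.diff(merged + [merged[0] + 2.0 * np.pi])
        arcs = (R * gaps).tolist()
        part.arcs_per_ring.append(arcs)
        ring_vars.append(_pop_var(arcs))
        ring_w.append(float(weights[j]))
    if not ring_vars:
        raise ValueError("no ring intersects any leaf skeleton")
    ring_w_arr = np.asarray(ring_w)
    ring_w_arr = ring_w_arr / ring_w_arr.sum()
    part.weights = ring_w_arr.tolist()
    value = float(ring_w_arr @ np.asarray(ring_vars))
    return (value, part) if return_partition else value


def height_consistency(skeleton: PlantSkeleton, reference: ReferenceLine) -> float:
    """Population variance across leaves of the mean keypoint height
    above the bottom reference line, px^2.

    Height is ``reference.row - y`` (positive above the line); keypoints
    below the line contribute negative heights.
    """
    if not skeleton.leaves:
        raise ValueError("height consistency needs at least one leaf")
    means = [float(np.mean(reference.row - lf.keypoints[:, 1])) for lf in skeleton.leaves]
    return _pop_var(means)


def phenotype_report(
    skeleton: PlantSkeleton,
    n_rings: int = 9,
    sigma: float | None = None,
) -> PhenotypeReport:
    """All phenotypes applicable to the skeleton's view.

    Quantities whose preconditions fail (e.g. fewer than two leaves for
    crown width) are left None rather than raising.
    """
    rep = PhenotypeReport(view=skeleton.view, leaf_count=leaf_count(skeleton))
    if skeleton.view == "top":
        if len(skeleton.leaves) >= 2:
            rep.crown_width = crown_width(skeleton)
            if skeleton.pot is not None:
                rep.relative_crown_width = relative_crown_width(rep.crown_width, skeleton.pot)
                try:
                    rep.distribution_consistency = distribution_consistency(
                        skeleton, skeleton.pot, n_rings=n_rings, sigma=sigma
                    )
                except ValueError:
                    pass
        if skeleton.leaves:
            rep.length_consistency = length_consistency(skeleton)
    else:
        if skeleton.leaves and skeleton.reference is not None:
            rep.height_consistency = height_consistency(skeleton, skeleton.reference)
    return rep
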