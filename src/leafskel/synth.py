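"""Synthetic potted-plant renderer with exact ground truth.

Generates top-view and front-view RGB scenes of a single leafy plant —
green tapering leaves, a brown pot, a neutral grey background — together
with the true midrib curve of every leaf, so the whole pipeline
(segmentation, sampling, tracing, phenotyping, evaluation) can be tested
without any external imagery.

Top view: leaves radiate outward from the pot rim with jittered base
angles and gently bending midribs (quadratic lateral offset in a
leaf-local frame).  Front view: each midrib is a gently bowed parabolic
arc rising from the pot's top edge, its apex being the leaf tip, so
every consecutive ground-truth triple passes the arch (convexity) test
and the tip is the point farthest from the leaf base.  Leaf tips taper
to ~1 px half-width, which reproduces qualitatively the tip-sampling
loss caused by boundary erosion on narrow tips.

Everything is deterministic for a given ``rng_seed``.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import scipy.ndimage as ndi
from skimage.draw import disk, polygon

from .evaluation import TrueCurve
from .segmentation import PotCircle, ReferenceLine

__all__ = ["LeafSpec", "GroundTruthMidrib", "SyntheticPlant", "make_plant_top", "make_plant_front"]

_BACKGROUND = (118, 118, 118)
_POT_BROWN = (139, 94, 60)


def _disk_struct(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return yy * yy + xx * xx <= radius * radius


@dataclass
class LeafSpec:
    """Geometry of one synthetic leaf."""

    base: tuple[float, float]        # (x, y) px
    base_angle: float                # degrees, initial midrib direction
    length: float                    # px along the leaf axis
    curvature_amp: float             # 1/px, lateral quadratic bending coefficient
    base_halfwidth: float = 7.0      # px
    tip_halfwidth: float = 1.2      # px
    taper_power: float = 6.0

    def halfwidth(self, s: float) -> float:
        """Half-width at arc fraction s in [0, 1].

        Strap-leaf profile: nearly constant width along the blade, with a
        short taper to ~1 px over the outermost stretch (the narrow tip
        that boundary erosion wipes out).
        """
        return self.tip_halfwidth + (self.base_halfwidth - self.tip_halfwidth) * (
            1.0 - s**self.taper_power
        )


@dataclass
class GroundTruthMidrib:
    """True midrib of one leaf: dense polyline (tip first) plus the
    analytic curve in a frame where it is a graph y(x)."""

    polyline: np.ndarray                      # (N, 2), tip -> base
    curve: TrueCurve
    to_curve_x: Callable[[np.ndarray], float]  # world point -> curve abscissa
    spec: LeafSpec


@dataclass
class SyntheticPlant:
    """Rendered scene plus exact ground truth."""

    image: np.ndarray                 # (H, W, 3) uint8
    view: Literal["top", "front"]
    gt_midribs: list[GroundTruthMidrib]
    gt_pot: PotCircle | None
    gt_reference: ReferenceLine | None
    rng_seed: int
    gt_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def gt_count(self) -> int:
        return len(self.gt_midribs)

    @property
    def gt_crown_width(self) -> float:
        tips = np.array([m.polyline[0] for m in self.gt_midribs])
        if len(tips) < 2:
            return 0.0
        diff = tips[:, None, :] - tips[None, :, :]
        return float(np.hypot(diff[..., 0], diff[..., 1]).max())


def _leaf_color(rng: np.random.Generator) -> tuple[int, int, int]:
    """A leaf-green RGB whose hue stays inside the 35-85 degree gate."""
    h = rng.uniform(48.0, 75.0) / 360.0
    s = rng.uniform(0.65, 0.85)
    v = rng.uniform(0.45, 0.65)
    r, g, b = colorsys.hsv_to_rgb(h, s, v)
    return int(round(r * 255)), int(round(g * 255)), int(round(b * 255))


def _midrib_points_top(spec: LeafSpec, n: int = 200) -> np.ndarray:
    """Dense midrib polyline, base -> tip, in image coordinates."""
    u = np.linspace(0.0, spec.length, n)
    v = 0.5 * spec.curvature_amp * u**2
    ang = np.radians(spec.base_angle)
    e = np.array([np.cos(ang), np.sin(ang)])
    nvec = np.array([-np.sin(ang), np.cos(ang)])
    return np.asarray(spec.base, float) + u[:, None] * e + v[:, None] * nvec


def _render_leaf(img: np.ndarray, mask: np.ndarray, midrib: np.ndarray,
                 spec: LeafSpec, color: tuple[int, int, int]) -> None:
    """Paint a tapering ribbon around the midrib into image and mask."""
    d = np.gradient(midrib, axis=0)
    norm = np.hypot(d[:, 0], d[:, 1])
    norm[norm == 0] = 1.0
    nvec = np.column_stack([-d[:, 1] / norm, d[:, 0] / norm])
    s = np.linspace(0.0, 1.0, len(midrib))
    w = np.array([spec.halfwidth(t) for t in s])
    left = midrib + w[:, None] * nvec
    right = midrib - w[:, None] * nvec
    poly = np.vstack([left, right[::-1]])
    rr, cc = polygon(poly[:, 1], poly[:, 0], shape=img.shape[:2])
    img[rr, cc] = color
    mask[rr, cc] = True


def make_plant_top(
    n_leaves: int,
    pot_radius: float = 70.0,
    image_side: int = 640,
    overlap_level: Literal["none", "mild", "heavy"] = "none",
    rng_seed: int = 0,
    noise: Literal["none", "speckle"] = "none",
    max_retries: int = 20,
) -> SyntheticPlant:
    """Top-view plant: ``n_leaves`` leaves radiating from the pot rim.

    ``overlap_level`` scales the angular jitter: "none" guarantees
    pairwise-disjoint leaf regions (verified, with retries), "mild"
    allows neighbouring leaves to touch along their flanks, "heavy"
    additionally bends and crowds them.  Raises RuntimeError when a
    disjoint packing cannot be found within ``max_retries``.
    """
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    rng = np.random.default_rng(rng_seed)
    H = W = int(image_side)
    center = np.array([W / 2.0, H / 2.0])
    spacing = 360.0 / n_leaves
    jitter_frac = {"none": 0.10, "mild": 0.28, "heavy": 0.45}[overlap_level]
    # geometry stays proportional to the canvas so rescaled scenes are
    # geometrically similar (margins in px, curvature in 1/px)
    rel = image_side / 640.0
    curve_max = {"none": 0.0012, "mild": 0.0015, "heavy": 0.0022}[overlap_level] / rel
    margin = 18.0 * rel
    max_len = W / 2.0 - pot_radius * 0.85 - margin

    for attempt in range(max_retries):
        specs: list[LeafSpec] = []
        midribs: list[np.ndarray] = []
        for k in range(n_leaves):
            ang = k * spacing + rng.uniform(-jitter_frac, jitter_frac) * spacing
            length = rng.uniform(0.6, 1.0) * max_len
            length = max(length, 110.0 * rel) if max_len >= 110.0 * rel else length
            base = center + pot_radius * 0.85 * np.array(
                [np.cos(np.radians(ang)), np.sin(np.radians(ang))]
            )
            spec = LeafSpec(
                base=(float(base[0]), float(base[1])),
                base_angle=float(ang),
                length=float(length),
                curvature_amp=float(rng.uniform(-curve_max, curve_max)),
                base_halfwidth=float(rng.uniform(6.0, 8.5)),
            )
            specs.append(spec)
            midribs.append(_midrib_points_top(spec))
        if overlap_level != "none":
            break
        # verify pairwise-disjoint rendered regions
        masks = []
        for spec, mid in zip(specs, midribs):
            m = np.zeros((H, W), dtype=bool)
            _render_leaf(np.zeros((H, W, 3), np.uint8), m, mid, spec, (0, 255, 0))
            masks.append(m)
        ok = True
        for i in range(n_leaves):
            for j in range(i + 1, n_leaves):
                if (masks[i] & masks[j]).any():
                    ok = False
                    break
            if not ok:
                break
        if ok:
            break
    else:
        raise RuntimeError("could not pack leaves without overlap; fewer leaves needed")

    img = np.empty((H, W, 3), dtype=np.uint8)
    img[...] = _BACKGROUND
    rr, cc = disk((H / 2.0, W / 2.0), pot_radius, shape=(H, W))
    img[rr, cc] = _POT_BROWN
    gt_mask = np.zeros((H, W), dtype=bool)
    gts: list[GroundTruthMidrib] = []
    for spec, mid in zip(specs, midribs):
        _render_leaf(img, gt_mask, mid, spec, _leaf_color(rng))
        ang = np.radians(spec.base_angle)
        e = np.array([np.cos(ang), np.sin(ang)])
        base = np.asarray(spec.base)
        c = spec.curvature_amp
        curve = TrueCurve(
            y=lambda x, c=c: 0.5 * c * x * x,
            dy=lambda x, c=c: c * x,
            ddy=lambda x, c=c: c,
            domain=(0.0, spec.length),
        )
        gts.append(
            GroundTruthMidrib(
                polyline=mid[::-1].copy(),  # tip first
                curve=curve,
                to_curve_x=lambda p, base=base, e=e: float((np.asarray(p, float) - base) @ e),
                spec=spec,
            )
        )
    if noise == "speckle":
        _add_speckle(img, rng)
    return SyntheticPlant(
        image=img, view="top", gt_midribs=gts,
        gt_pot=PotCircle(center=(W / 2.0, H / 2.0), radius=pot_radius),
        gt_reference=None, rng_seed=rng_seed, gt_mask=gt_mask,
    )


def _add_speckle(img: np.ndarray, rng: np.random.Generator, n_spots: int = 40) -> None:
    """Small green-hued background dots (exercise opening / area filters)."""
    H, W = img.shape[:2]
    for _ in range(n_spots):
        y, x = rng.integers(0, H), rng.integers(0, W)
        r = int(rng.integers(1, 3))
        rr, cc = disk((y, x), r, shape=(H, W))
        img[rr, cc] = (90, 140, 60)


def make_plant_front(
    n_leaves: int,
    image_side: int = 896,
    rng_seed: int = 0,
    pot_width: float = 320.0,
    pot_height: float = 130.0,
    max_retries: int = 30,
) -> SyntheticPlant:
    """Front-view plant: arch-shaped strap leaves rising from the pot top.

    Each midrib is a gently bowed parabolic arc — a graph y(x) in image
    coordinates whose apex is the leaf tip — anchored on the pot's top
    row.  Every consecutive ground-truth triple passes the arch
    (convexity) test, and the leaf tip is the point farthest from the
    leaf base, matching the tracer's initialisation rule.  Leaves
    alternate sides and fan outward; rendered regions are verified to be
    pairwise disjoint (with retries)."""
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    rng = np.random.default_rng(rng_seed)
    H = W = int(image_side)
    y_ref = int(H - pot_height - 8)
    pot_x0 = W / 2.0 - pot_width / 2.0
    per_side = (n_leaves + 1) // 2

    for attempt in range(max_retries):
        specs: list[tuple] = []
        midribs: list[np.ndarray] = []
        for k in range(n_leaves):
            sgn = 1 if k % 2 == 0 else -1
            m = k // 2
            step = 0.5 if per_side <= 1 else m / (per_side - 1.0)
            # fan arrangement: inner leaves near-vertical and tall, outer
            # leaves leaning farther out and lower, so arcs nest without crossing
            dx = 135.0 + 135.0 * step + rng.uniform(-8.0, 8.0)
            h = 560.0 - 210.0 * step + rng.uniform(-14.0, 14.0)
            h = min(h, y_ref - 25.0)
            base_x = W / 2.0 + sgn * (14.0 + (pot_width / 2.0 - 30.0) * step
                                      + rng.uniform(-4.0, 4.0))
            dx = min(dx, (W - 12.0 - base_x) if sgn > 0 else (base_x - 12.0))
            a = h / dx**2  # row(u) = y_ref - h + a (u - dx)^2, u in [0, dx]
            spec = LeafSpec(
                base=(float(base_x), float(y_ref)),
                base_angle=90.0,
                length=float(dx),
                curvature_amp=float(a),
                base_halfwidth=float(rng.uniform(4.0, 5.0)),
                tip_halfwidth=1.0,
            )
            u = np.linspace(0.0, dx, 200)
            x = base_x + sgn * u
            y = y_ref - h + a * (u - dx) ** 2
            specs.append((spec, sgn, dx, h))
            midribs.append(np.column_stack([x, y]))  # base -> tip
        masks = []
        for (spec, *_), mid in zip(specs, midribs):
            msk = np.zeros((H, W), dtype=bool)
            _render_leaf(np.zeros((H, W, 3), np.uint8), msk, mid, spec, (0, 255, 0))
            masks.append(ndi.binary_dilation(msk, structure=_disk_struct(5)))
        ok = all(
            not (masks[i] & masks[j]).any()
            for i in range(n_leaves) for j in range(i + 1, n_leaves)
        )
        if ok:
            break
    else:
        raise RuntimeError("could not pack front-view leaves without overlap")

    img = np.empty((H, W, 3), dtype=np.uint8)
    img[...] = _BACKGROUND
    img[y_ref:int(y_ref + pot_height), int(pot_x0):int(pot_x0 + pot_width)] = _POT_BROWN
    gt_mask = np.zeros((H, W), dtype=bool)
    gts: list[GroundTruthMidrib] = []
    for (spec, sgn, dx, h), mid in zip(specs, midribs):
        _render_leaf(img, gt_mask, mid, spec, _leaf_color(rng))
        base_x = spec.base[0]
        a = spec.curvature_amp
        lo, hi = (min(mid[0, 0], mid[-1, 0]), max(mid[0, 0], mid[-1, 0]))
        curve = TrueCurve(
            y=lambda xx, a=a, b=base_x, s=sgn, ua=dx, yr=y_ref, hh=h:
                yr - hh + a * (s * (xx - b) - ua) ** 2,
            dy=lambda xx, a=a, b=base_x, s=sgn, ua=dx:
                2.0 * a * (s * (xx - b) - ua) * s,
            ddy=lambda xx, a=a: 2.0 * a,
            domain=(float(lo), float(hi)),
        )
        gts.append(
            GroundTruthMidrib(
                polyline=mid[::-1].copy(),
                curve=curve,
                to_curve_x=lambda p: float(np.asarray(p, float)[0]),
                spec=spec,
            )
        )
    return SyntheticPlant(
        image=img, view="front", gt_midribs=gts, gt_pot=None,
        gt_reference=ReferenceLine(row=y_ref), rng_seed=rng_seed, gt_mask=gt_mask,
    )
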