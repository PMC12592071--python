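"""Leaf segmentation: colour thresholding, morphological clean-up and
contour-shape filtering, plus pot-circle / bottom-reference estimation.

An RGB image of a single potted plant is turned into a binary leaf mask in
three steps: (1) an HSV hue gate keeps green pixels; (2) morphological
closing then opening bridges intra-leaf gaps and removes background
speckle; (3) connected regions are kept only if they are large enough
(area >= ``area_min``) and elongated enough (minimum-area bounding
rectangle aspect ratio > ``ar_min``), since leaves are much longer than
wide.  The final mask is the intersection of the cleaned mask with the
filled, retained contours.

Coordinates: x = column, y = row, origin top-left, y grows downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from shapely import MultiPoint
from skimage import measure
from skimage.color import rgb2hsv

__all__ = [
    "ContourRecord",
    "PotCircle",
    "ReferenceLine",
    "hsv_mask",
    "refine_mask",
    "filter_contours",
    "estimate_pot_circle",
    "estimate_reference_line",
]


@dataclass(frozen=True)
class PotCircle:
    """Circle covering the flowerpot in top view: anchor for tip selection,
    sampling exclusion and trace termination."""

    center: tuple[float, float]  # (x, y) px
    radius: float                # px

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("pot radius must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return np.hypot(pts[:, 0] - self.center[0], pts[:, 1] - self.center[1]) <= self.radius


@dataclass(frozen=True)
class ReferenceLine:
    """Horizontal bottom reference in front view (top edge of the pot).

    ``from_fallback`` flags that no pot was found and the bottom-most
    foreground row of the leaf mask was used instead.
    """

    row: int
    from_fallback: bool = False


@dataclass(frozen=True)
class ContourRecord:
    """External contour of one connected leaf-candidate region."""

    boundary: np.ndarray          # ordered (x, y) boundary vertices, closed loop
    area: float                   # px^2 of the filled region
    bounding_rect: tuple          # ((cx, cy), (long_side, short_side), angle_deg)
    aspect_ratio: float           # long side / short side, >= 1
    perimeter: float              # boundary length, px
    label: int                    # connected-component label in the source mask

    def length(self, mode: str = "bbox") -> float:
        """Characteristic contour length: rect long side or perimeter."""
        if mode == "bbox":
            return self.bounding_rect[1][0]
        if mode == "perimeter":
            return self.perimeter
        raise ValueError(f"unknown length mode {mode!r}")


def _square(side: int) -> np.ndarray:
    return np.ones((side, side), dtype=bool)


def _erode(mask: np.ndarray, side: int) -> np.ndarray:
    # pad with foreground so the image border is never eroded
    return ndi.binary_erosion(mask, structure=_square(side), border_value=1)


def _dilate(mask: np.ndarray, side: int) -> np.ndarray:
    return ndi.binary_dilation(mask, structure=_square(side), border_value=0)


def hsv_mask(
    image: np.ndarray,
    hue_min: float = 35.0,
    hue_max: float = 85.0,
    sat_floor: float = 40.0 / 255.0,
    val_floor: float = 40.0 / 255.0,
) -> np.ndarray:
    """Initial binary mask: pixels whose hue lies in [hue_min, hue_max] degrees.

    Saturation and value floors (fractions of 1) keep grey/black pixels —
    whose hue is numerically arbitrary — out of the foreground.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise ValueError("expected a non-empty H x W x 3 RGB image")
    if not (0.0 <= hue_min < hue_max <= 360.0):
        raise ValueError("require 0 <= hue_min < hue_max <= 360")
    hsv = rgb2hsv(image)
    hue = hsv[..., 0] * 360.0
    return (
        (hue >= hue_min)
        & (hue <= hue_max)
        & (hsv[..., 1] >= sat_floor)
        & (hsv[..., 2] >= val_floor)
    )


def refine_mask(mask: np.ndarray, kernel_side: int = 5) -> np.ndarray:
    """Morphological closing followed by opening with a square all-ones kernel.

    Closing bridges small gaps and holes inside leaves; opening removes
    speckle noise.  Erosion treats pixels outside the image as foreground
    and dilation treats them as background, so all-true and all-false
    masks are fixed points.
    """
    if kernel_side < 3 or kernel_side % 2 == 0:
        raise ValueError("kernel_side must be odd and >= 3")
    mask = np.asarray(mask, dtype=bool)
    closed = _erode(_dilate(mask, kernel_side), kernel_side)
    return _dilate(_erode(closed, kernel_side), kernel_side)


def _min_area_rect(coords_xy: np.ndarray) -> tuple[tuple, tuple, float]:
    """Minimum-area rotated bounding rectangle of a point set.

    Returns ((cx, cy), (long_side, short_side), angle_deg) where angle is
    the orientation of the long side.
    """
    mp = MultiPoint(coords_xy)
    rect = mp.minimum_rotated_rectangle
    if rect.geom_type != "Polygon":  # degenerate: collinear or single point
        xs, ys = coords_xy[:, 0], coords_xy[:, 1]
        length = float(np.hypot(xs.max() - xs.min(), ys.max() - ys.min()))
        cx, cy = float(xs.mean()), float(ys.mean())
        ang = float(np.degrees(np.arctan2(ys.max() - ys.min(), xs.max() - xs.min())))
        return (cx, cy), (length, 0.0), ang
    corners = np.asarray(rect.exterior.coords)[:4]
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    s1, s2 = float(np.hypot(*e1)), float(np.hypot(*e2))
    cx, cy = map(float, corners.mean(axis=0))
    if s1 >= s2:
        long_side, short_side, evec = s1, s2, e1
    else:
        long_side, short_side, evec = s2, s1, e2
    ang = float(np.degrees(np.arctan2(evec[1], evec[0])))
    return (cx, cy), (long_side, short_side), ang


def filter_contours(
    mask: np.ndarray,
    area_min: float = 500.0,
    ar_min: float = 2.0,
) -> tuple[list[ContourRecord], np.ndarray]:
    """Keep external contours of large, elongated regions.

    Connected components (8-connectivity) are filled (external contour
    semantics), then kept iff filled area >= ``area_min`` and min-area
    bounding-rect aspect ratio > ``ar_min``.  Returns the retained
    contour records and the union mask of the filled retained regions;
    the caller intersects it with the refined mask to obtain the final
    leaf mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty mask")
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    records: list[ContourRecord] = []
    keep = np.zeros_like(mask)
    for lab in range(1, n + 1):
        comp = labels == lab
        filled = ndi.binary_fill_holes(comp)
        area = float(filled.sum())
        if area < area_min:
            continue
        ys, xs = np.nonzero(filled)
        # +-0.5 pixel corners so 1-px-thin regions get a nonzero short side
        pts = np.column_stack([xs, ys]).astype(float)
        corners = np.concatenate(
            [pts + off for off in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))]
        )
        rect = _min_area_rect(corners)
        long_side, short_side = rect[1]
        ar = float("inf") if short_side == 0 else long_side / short_side
        if not ar > ar_min:
            continue
        contours = measure.find_contours(filled.astype(float), 0.5)
        boundary_rc = max(contours, key=len) if contours else np.column_stack([ys, xs])
        boundary = boundary_rc[:, ::-1].copy()  # (row, col) -> (x, y)
        perim = float(np.hypot(*np.diff(boundary, axis=0).T).sum())
        records.append(
            ContourRecord(
                boundary=boundary,
                area=area,
                bounding_rect=rect,
                aspect_ratio=ar,
                perimeter=perim,
                label=lab,
            )
        )
        keep |= filled
    return records, keep


def estimate_pot_circle(
    leaf_mask: np.ndarray,
    contours: list[ContourRecord],
    mode: str = "bbox",
) -> PotCircle:
    """Pot-covering circle: centroid of the leaf mask, radius half the
    length of the shortest retained contour.

    "Length" defaults to the long side of the contour's minimum-area
    bounding rectangle (a leaf's length); ``mode="perimeter"`` uses the
    boundary length instead.
    """
    if not contours:
        raise ValueError("no contours to estimate the pot circle from")
    leaf_mask = np.asarray(leaf_mask, dtype=bool)
    ys, xs = np.nonzero(leaf_mask)
    if len(xs) == 0:
        raise ValueError("empty leaf mask")
    center = (float(xs.mean()), float(ys.mean()))
    radius = 0.5 * min(c.length(mode) for c in contours)
    return PotCircle(center=center, radius=radius)


def estimate_reference_line(
    image: np.ndarray | None = None,
    leaf_mask: np.ndarray | None = None,
    pot_hint: int | None = None,
    pot_hue: tuple[float, float] = (5.0, 35.0),
    min_pot_area: float = 200.0,
) -> ReferenceLine:
    """Bottom reference row for front-view images.

    Priority: an explicit ``pot_hint`` row; else the top edge of the
    bounding rectangle of the largest pot-coloured (brown-hued) region in
    ``image``; else the bottom-most foreground row of ``leaf_mask``
    (flagged via ``from_fallback``).
    """
    if pot_hint is not None:
        return ReferenceLine(row=int(pot_hint))
    if image is not None:
        pot = hsv_mask(image, pot_hue[0], pot_hue[1])
        labels, n = ndi.label(pot, structure=np.ones((3, 3), dtype=int))
        if n:
            sizes = ndi.sum_labels(pot, labels, index=np.arange(1, n + 1))
            best = int(np.argmax(sizes)) + 1
            if float(sizes[best - 1]) >= min_pot_area:
                rows = np.nonzero(labels == best)[0]
                return ReferenceLine(row=int(rows.min()))
    if leaf_mask is not None:
        ys = np.nonzero(np.asarray(leaf_mask, bool))[0]
        if len(ys):
            return ReferenceLine(row=int(ys.max()), from_fallback=True)
    raise ValueError("cannot estimate a reference line without a pot or a non-empty mask")
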