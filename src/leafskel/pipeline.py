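"""End-to-end composition: image -> leaf mask -> seed points -> skeleton
-> phenotypes, plus evaluation against ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import evaluation as ev
from .config import PipelineConfig
from .phenotypes import PhenotypeReport, phenotype_report
from .sampling import SeedPointSet, erode_boundary, stratified_sample
from .segmentation import (
    ContourRecord,
    PotCircle,
    ReferenceLine,
    estimate_pot_circle,
    estimate_reference_line,
    filter_contours,
    hsv_mask,
    refine_mask,
)
from .tracing import PlantSkeleton, TraceParams, trace_all

__all__ = ["PipelineResult", "EmptyMaskError", "NoLeavesError", "run_pipeline", "evaluate_skeleton"]


class EmptyMaskError(RuntimeError):
    """Segmentation produced no leaf pixels."""


class NoLeavesError(RuntimeError):
    """Tracing produced no accepted polylines."""


@dataclass
class PipelineResult:
    skeleton: PlantSkeleton
    report: PhenotypeReport
    leaf_mask: np.ndarray
    eroded_mask: np.ndarray
    points: SeedPointSet           # post-trace visited state
    contours: list[ContourRecord]
    pot: PotCircle | None
    reference: ReferenceLine | None


def trace_params_from_config(config: PipelineConfig, image_shape: tuple[int, int]) -> TraceParams:
    baseline = config.dir_baseline
    if baseline is None:
        # direction estimates span at least two sampling cells, keeping the
        # angular noise from lateral seed jitter well below theta_max
        baseline = 2.0 * max(image_shape[0], image_shape[1]) / config.grid
    return TraceParams(
        r0=config.r0,
        r_step=config.r_step,
        r_max=config.r_max,
        theta_max=config.theta_max,
        min_keypoints=config.min_keypoints,
        consume_width=config.consume_width,
        dir_baseline=baseline,
        halfplane_mode=config.halfplane_mode,
    ).resolved(image_shape)


def run_pipeline(
    image: np.ndarray,
    view: str,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run segmentation, sampling, tracing and phenotyping on one image.

    Raises :class:`EmptyMaskError` when no leaf pixels survive
    segmentation and :class:`NoLeavesError` when tracing yields no
    polyline.
    """
    if view not in ("top", "front"):
        raise ValueError("view must be 'top' or 'front'")
    if config is None:
        config = PipelineConfig()
    image = np.asarray(image)

    mask0 = hsv_mask(image, config.hue_min, config.hue_max, config.sat_floor, config.val_floor)
    refined = refine_mask(mask0, config.kernel_side)
    if not refined.any():
        raise EmptyMaskError("no foreground after colour thresholding and morphology")
    contours, keep = filter_contours(refined, config.area_min, config.ar_min)
    leaf_mask = refined & keep
    if not contours or not leaf_mask.any():
        raise EmptyMaskError("no contour survives the area / aspect-ratio filters")

    pot: PotCircle | None = None
    reference: ReferenceLine | None = None
    if view == "top":
        pot = estimate_pot_circle(leaf_mask, contours, mode=config.pot_radius_mode)
    else:
        reference = estimate_reference_line(image=image, leaf_mask=leaf_mask)

    eroded = erode_boundary(leaf_mask, config.erosion_iterations, config.kernel_side)
    points = stratified_sample(
        eroded,
        grid=config.grid,
        pot=pot if view == "top" else None,
        rng_seed=config.rng_seed,
        on_mask_bbox=config.grid_on_mask_bbox,
    )
    params = trace_params_from_config(config, image.shape[:2])
    skeleton = trace_all(points, view, pot=pot, reference=reference, params=params)
    if not skeleton.leaves:
        raise NoLeavesError("tracing produced no leaf polyline")
    report = phenotype_report(skeleton, n_rings=config.n_rings, sigma=config.sigma)
    return PipelineResult(
        skeleton=skeleton, report=report, leaf_mask=leaf_mask, eroded_mask=eroded,
        points=points, contours=contours, pot=pot, reference=reference,
    )


def _mean_polyline_distance(kp: np.ndarray, gt_poly: np.ndarray) -> float:
    from ._geometry import point_segment_distance

    dmin = np.full(len(kp), np.inf)
    for a, b in zip(gt_poly[:-1], gt_poly[1:]):
        dmin = np.minimum(dmin, point_segment_distance(kp, a, b))
    return float(dmin.mean())


def evaluate_skeleton(skeleton: PlantSkeleton, gt_midribs, gt_count: int | None = None) -> "ev.EvalReport":
    """Score a traced skeleton against ground-truth midribs.

    Each predicted polyline is matched to the ground-truth midrib with
    the smallest mean vertex-to-midrib distance; the curvature error is
    averaged over matched polylines long enough for the discrete
    curvature stencil (>= 5 vertices).
    """
    if gt_count is None:
        gt_count = len(gt_midribs)
    recall = ev.leaf_recall(len(skeleton.leaves), gt_count)
    errors: list[float] = []
    for lf in skeleton.leaves:
        kp = np.asarray(lf.keypoints, float)
        best = min(gt_midribs, key=lambda m: _mean_polyline_distance(kp, m.polyline))
        if len(kp) >= 5:
            try:
                errors.append(ev.curvature_error(best.curve, kp, to_domain=best.to_curve_x))
            except ValueError:
                pass
    cerr = float(np.mean(errors)) if errors else None
    return ev.EvalReport(curvature_error=cerr, leaf_recall=recall, tip_missed=[])
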