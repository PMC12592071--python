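"""Seed-point generation: boundary erosion plus stratified grid sampling.

Eroding the leaf mask pulls candidate pixels away from leaf edges so that
sampled points sit near the central skeleton; a fixed grid then yields at
most one uniformly drawn point per cell, giving an even spatial spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .segmentation import PotCircle

__all__ = ["SeedPointSet", "erode_boundary", "stratified_sample"]


@dataclass
class SeedPointSet:
    """Sampled interior points with per-point visited bookkeeping.

    ``points`` is an (N, 2) integer array of (x, y) pixel coordinates;
    ``visited`` marks points already claimed by a traced leaf.
    """

    points: np.ndarray
    rng_seed: int
    visited: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.visited is None:
            self.visited = np.zeros(len(self.points), dtype=bool)
        else:
            self.visited = np.asarray(self.visited, dtype=bool)
        if len(self.visited) != len(self.points):
            raise ValueError("visited length must match point count")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def unvisited_indices(self) -> np.ndarray:
        return np.nonzero(~self.visited)[0]

    def mark_visited(self, index: int) -> None:
        self.visited[index] = True

    def copy(self) -> "SeedPointSet":
        return SeedPointSet(self.points.copy(), self.rng_seed, self.visited.copy())


def erode_boundary(mask: np.ndarray, iterations: int = 1, kernel_side: int = 5) -> np.ndarray:
    """Shrink the mask away from leaf boundaries.

    Plain morphological erosion with a square all-ones kernel, applied
    ``iterations`` times; out-of-image pixels count as foreground so the
    image border itself does not erode the mask.  ``iterations=0`` is the
    identity.  The output is always a subset of the input.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if iterations == 0:
        return mask.copy()
    structure = np.ones((kernel_side, kernel_side), dtype=bool)
    return ndi.binary_erosion(mask, structure=structure, iterations=iterations, border_value=1)


def stratified_sample(
    mask: np.ndarray,
    grid: int = 40,
    pot: PotCircle | None = None,
    rng_seed: int = 0,
    on_mask_bbox: bool = False,
) -> SeedPointSet:
    """One uniformly drawn foreground pixel per grid cell.

    The image (or, with ``on_mask_bbox``, the mask's bounding box) is
    partitioned into ``grid`` x ``grid`` cells.  Each cell containing at
    least one eligible pixel — foreground and, if ``pot`` is given,
    outside the pot circle — contributes exactly one point, drawn
    uniformly from its eligible pixels.  Deterministic for a given
    ``rng_seed``; cells are visited in row-major order.
    """
    if grid < 1:
        raise ValueError("grid must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    eligible = mask.copy()
    if pot is not None:
        ys, xs = np.nonzero(mask)
        if len(xs):
            inside = pot.contains(np.column_stack([xs, ys]).astype(float))
            eligible[ys[inside], xs[inside]] = False

    if on_mask_bbox and eligible.any():
        ys, xs = np.nonzero(eligible)
        y0, y1, x0, x1 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
    else:
        y0, y1, x0, x1 = 0, H, 0, W

    row_edges = np.linspace(y0, y1, grid + 1).round().astype(int)
    col_edges = np.linspace(x0, x1, grid + 1).round().astype(int)
    rng = np.random.default_rng(rng_seed)
    points: list[tuple[int, int]] = []
    for gi in range(grid):
        for gj in range(grid):
            cell = eligible[row_edges[gi]:row_edges[gi + 1], col_edges[gj]:col_edges[gj + 1]]
            ys_c, xs_c = np.nonzero(cell)
            if len(xs_c) == 0:
                continue
            k = int(rng.integers(len(xs_c)))
            points.append((col_edges[gj] + int(xs_c[k]), row_edges[gi] + int(ys_c[k])))
    pts = np.array(points, dtype=float).reshape(-1, 2)
    return SeedPointSet(points=pts, rng_seed=rng_seed)
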