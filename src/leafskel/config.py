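"""Pipeline configuration.

One flat, file-serialisable record holds every constant the pipeline uses:
the global segmentation/sampling/tracing parameters that are applied
unchanged to all images, plus the implementation knobs this package adds
(search-radius growth, ring count for the distribution phenotype, ...).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Global parameters applied to every image.

    The first block mirrors the method's fixed parameter set; the second
    block holds knobs the method leaves unspecified, with this package's
    defaults.
    """

    # --- fixed method parameters -------------------------------------
    hue_min: float = 35.0          # degrees, lower green-hue bound
    hue_max: float = 85.0          # degrees, upper green-hue bound
    kernel_side: int = 5           # px, square structuring element
    erosion_iterations: int = 1    # boundary-erosion passes before sampling
    area_min: float = 500.0        # px^2, contour area cut-off
    ar_min: float = 2.0            # min bounding-rect aspect ratio (exclusive)
    grid: int = 40                 # stratified-sampling patches per side
    r0: float = 5.0                # px, initial search radius
    theta_max: float = 20.0        # degrees, angle-difference threshold

    # --- implementation knobs ----------------------------------------
    sat_floor: float = 40.0 / 255.0   # min HSV saturation for foreground
    val_floor: float = 40.0 / 255.0   # min HSV value for foreground
    r_step: float = 5.0               # px, search-radius growth per expansion
    r_max: float | None = None        # px cap; None -> image diagonal / 4
    min_keypoints: int = 3            # shortest polyline kept
    consume_width: float = 12.0       # px, post-trace point-consumption corridor
    dir_baseline: float | None = None # px, direction-estimate baseline; None -> 2 grid cells
    n_rings: int = 9                  # concentric rings for distribution consistency
    sigma: float | None = None        # Gaussian ring-weight width; None -> n_rings/4
    halfplane_mode: str = "axis"      # "axis" | "vector"
    pot_radius_mode: str = "bbox"     # "bbox" (rect long side) | "perimeter"
    grid_on_mask_bbox: bool = False   # grid over mask bbox instead of full image
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.hue_min < self.hue_max <= 360.0):
            raise ValueError("require 0 <= hue_min < hue_max <= 360")
        if self.kernel_side < 3 or self.kernel_side % 2 == 0:
            raise ValueError("kernel_side must be odd and >= 3")
        if self.halfplane_mode not in ("axis", "vector"):
            raise ValueError("halfplane_mode must be 'axis' or 'vector'")
        if self.pot_radius_mode not in ("bbox", "perimeter"):
            raise ValueError("pot_radius_mode must be 'bbox' or 'perimeter'")

    # --- serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
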