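"""Reading and writing pipeline artefacts.

Images go through Pillow; skeletons and evaluation reports are JSON;
phenotypes are one-row CSV records (pandas).  Overlay PNGs show the
traced polylines and seed points on top of the source image for visual
inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .phenotypes import PhenotypeReport
from .sampling import SeedPointSet
from .segmentation import PotCircle, ReferenceLine
from .tracing import LeafPolyline, PlantSkeleton

__all__ = [
    "load_image",
    "save_mask_png",
    "save_points_csv",
    "skeleton_to_dict",
    "skeleton_from_dict",
    "save_skeleton_json",
    "load_skeleton_json",
    "save_phenotypes_csv",
    "save_overlay_png",
]


def load_image(path: str | Path) -> np.ndarray:
    """RGB uint8 array from a PNG/JPEG file."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)


def save_points_csv(points: SeedPointSet, path: str | Path) -> None:
    pd.DataFrame(points.points, columns=["x", "y"]).to_csv(path, index=False)


def skeleton_to_dict(skeleton: PlantSkeleton) -> dict:
    d: dict = {
        "view": skeleton.view,
        "leaves": [
            {"leaf_id": lf.leaf_id, "keypoints": np.asarray(lf.keypoints).tolist()}
            for lf in skeleton.leaves
        ],
    }
    if skeleton.pot is not None:
        d["pot"] = {"center": list(skeleton.pot.center), "radius": skeleton.pot.radius}
    if skeleton.reference is not None:
        d["reference"] = {
            "row": skeleton.reference.row,
            "from_fallback": skeleton.reference.from_fallback,
        }
    return d


def skeleton_from_dict(d: dict) -> PlantSkeleton:
    pot = None
    if "pot" in d:
        pot = PotCircle(center=tuple(d["pot"]["center"]), radius=float(d["pot"]["radius"]))
    ref = None
    if "reference" in d:
        ref = ReferenceLine(
            row=int(d["reference"]["row"]),
            from_fallback=bool(d["reference"].get("from_fallback", False)),
        )
    leaves = [
        LeafPolyline(keypoints=np.asarray(lf["keypoints"], float), leaf_id=int(lf["leaf_id"]))
        for lf in d["leaves"]
    ]
    return PlantSkeleton(leaves=leaves, view=d["view"], pot=pot, reference=ref)


def save_skeleton_json(skeleton: PlantSkeleton, path: str | Path) -> None:
    Path(path).write_text(json.dumps(skeleton_to_dict(skeleton), indent=2, sort_keys=True))


def load_skeleton_json(path: str | Path) -> PlantSkeleton:
    return skeleton_from_dict(json.loads(Path(path).read_text()))


def save_phenotypes_csv(report: PhenotypeReport, path: str | Path, image: str = "") -> None:
    row = {"image": image, **report.to_dict()}
    pd.DataFrame([row]).to_csv(path, index=False)


def save_overlay_png(
    image: np.ndarray,
    path: str | Path,
    skeleton: PlantSkeleton | None = None,
    points: SeedPointSet | None = None,
) -> None:
    """Source image with seed points (yellow) and polylines (red) drawn on."""
    im = Image.fromarray(np.asarray(image, np.uint8)).convert("RGB")
    draw = ImageDraw.Draw(im)
    if points is not None:
        for x, y in points.points:
            draw.ellipse([x - 1.5, y - 1.5, x + 1.5, y + 1.5], fill=(255, 220, 0))
    if skeleton is not None:
        for lf in skeleton.leaves:
            kp = [(float(x), float(y)) for x, y in lf.keypoints]
            if len(kp) >= 2:
                draw.line(kp, fill=(230, 30, 30), width=2)
            draw.ellipse(
                [kp[0][0] - 3, kp[0][1] - 3, kp[0][0] + 3, kp[0][1] + 3],
                outline=(30, 80, 255), width=2,
            )
        if skeleton.pot is not None:
            (cx, cy), r = skeleton.pot.center, skeleton.pot.radius
            draw.ellipse([cx - r, cy - r, cx + r, cy + r], outline=(30, 80, 255), width=2)
        if skeleton.reference is not None:
            draw.line([(0, skeleton.reference.row), (im.width, skeleton.reference.row)],
                      fill=(30, 80, 255), width=2)
    im.save(path)
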