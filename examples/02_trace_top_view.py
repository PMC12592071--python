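"""Trace every leaf midrib in a top-view scene and score the result.

Top-view (random morphology) tracing starts at the seed point farthest
from the pot, then repeatedly accepts the candidate whose turning-angle
difference stays within 20 degrees inside an expanding circular search
region, ending each leaf when the empty search circle reaches the pot.
"""

from leafskel import make_plant_top, run_pipeline
from leafskel.pipeline import evaluate_skeleton

plant = make_plant_top(8, rng_seed=0)
result = run_pipeline(plant.image, "top")
report = evaluate_skeleton(result.skeleton, plant.gt_midribs)

print(f"true leaves: {plant.gt_count}, traced polylines: {len(result.skeleton.leaves)}")
print(f"leaf recall: {report.leaf_recall:.1f}%")
print(f"mean curvature error vs true midribs: {report.curvature_error:.4f} (1/px)")
for leaf in result.skeleton.leaves[:3]:
    tip = leaf.keypoints[0]
    print(f"  leaf {leaf.leaf_id}: {len(leaf.keypoints)} keypoints, tip at ({tip[0]:.0f}, {tip[1]:.0f})")
# Recall of 100% means every true leaf produced exactly one polyline; the
# curvature error compares discrete turning-angle curvature against the
# analytic curvature of the generating midrib curves.
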