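"""Segment a synthetic top-view plant and sample seed points.

Renders an 8-leaf plant, gates green hues in HSV, cleans the mask with
closing/opening and the area / aspect-ratio contour filters, estimates
the pot circle, then draws one random point per grid cell of the eroded
mask (excluding the pot).
"""

from leafskel import (
    erode_boundary,
    estimate_pot_circle,
    filter_contours,
    hsv_mask,
    make_plant_top,
    refine_mask,
    stratified_sample,
)

plant = make_plant_top(8, rng_seed=0)
mask = refine_mask(hsv_mask(plant.image))
contours, keep = filter_contours(mask)
leaf_mask = mask & keep
pot = estimate_pot_circle(leaf_mask, contours)
eroded = erode_boundary(leaf_mask)
points = stratified_sample(eroded, pot=pot, rng_seed=0)

print(f"leaf pixels after segmentation: {int(leaf_mask.sum())}")
print(f"retained contours (area >= 500 px^2, aspect ratio > 2): {len(contours)}")
print(f"estimated pot: centre ({pot.center[0]:.0f}, {pot.center[1]:.0f}), radius {pot.radius:.1f} px")
print(f"seed points (one per occupied 40x40-grid cell, pot excluded): {len(points)}")
# The pot radius is half the shortest retained contour's length, so it tracks
# the shortest leaf; the seed count is the number of grid cells the eroded
# leaf area touches.
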