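"""Extract the five geometric phenotypes from traced skeletons.

Top view gives leaf count, relative crown width (crown width over pot
diameter), leaf length consistency and leaf distribution consistency;
front view gives leaf height consistency.  Consistencies are population
variances in px^2 — smaller means a more uniform plant.
"""

from leafskel import make_plant_front, make_plant_top, run_pipeline

top = run_pipeline(make_plant_top(8, rng_seed=0).image, "top").report
front = run_pipeline(make_plant_front(6, rng_seed=1).image, "front").report

print("top view:")
print(f"  leaf count                 : {top.leaf_count}")
print(f"  crown width                : {top.crown_width:.1f} px")
print(f"  relative crown width       : {top.relative_crown_width:.2f}")
print(f"  leaf length consistency    : {top.length_consistency:.1f} px^2")
print(f"  leaf distribution consistency: {top.distribution_consistency:.1f} px^2")
print("front view:")
print(f"  leaf count                 : {front.leaf_count}")
print(f"  leaf height consistency    : {front.height_consistency:.1f} px^2")
# Relative crown width is scale-free (pot diameter as the ruler); the three
# consistency indices quantify how uniform the leaves are in length, angular
# spacing around the pot, and height above the pot rim.
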