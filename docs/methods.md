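# Methods

This note records the models, parameter choices and numerical decisions
behind `leafskel`, and what the synthetic-data tests do and do not
demonstrate about real images.

## Coordinate and unit conventions

Pixels throughout; x = column, y = row, origin top-left, y increases
downward, so "above" always means a smaller row index. Angles are
degrees in the tracing rules and radians inside the discrete-curvature
formula (radians make the straight-line limit exactly zero and give
curvature units of 1/px, commensurable with the analytic curvature).
All variances are population (divide-by-n) variances.

## Segmentation

The HSV gate keeps pixels with hue in [35°, 85°]; hue alone classifies
grey and black pixels arbitrarily, so saturation and value floors
(default 40/255 each, configurable) are applied as well. Mask clean-up
is closing followed by opening with a 5×5 all-ones kernel. Border
convention: erosion pads with foreground and dilation with background,
so the all-true and all-false masks are fixed points of the clean-up.
Connected components use 8-connectivity; only external contours matter,
so components are hole-filled before the area (≥ 500 px²) and
bounding-rectangle aspect-ratio (> 2) filters. The minimum-area rotated
rectangle is computed on the ±½-pixel corners of the component so that
one-pixel-thin regions get a non-zero short side.

The pot circle's radius is half the *length* of the shortest retained
contour. "Length" is read as the long side of the contour's minimum-area
rectangle — a leaf's length — rather than its perimeter, which would
nearly double the radius; `pot_radius_mode="perimeter"` switches the
reading. Consequently the estimated pot circle tracks the shortest
leaf, not the physical pot; the whole pipeline (sampling exclusion,
trace termination, relative crown width) consistently uses this same
estimate.

The front-view bottom reference line is the top edge of the largest
brown-hued (hue 5°–35°) region's bounding box; when no pot is found,
the bottom-most foreground row of the leaf mask is used and flagged.

## Seed sampling

One erosion pass (same 5×5 kernel) pulls candidate pixels toward the
midrib before one uniform random pixel is drawn per occupied cell of a
40×40 grid over the full image (a mask-bounding-box mode exists as a
config switch). Sampling is driven by a mandatory integer seed; given
the seed, the whole pipeline is deterministic. Cells wholly inside the
pot circle contribute nothing (top view only — in front view the pot is
below the reference line and is not excluded).

## Tracing

Both tracers share the outer loop: the next leaf's tip is the unvisited
point farthest from the anchor (pot centre in top view, leaf-base point
on the reference line in front view); ties break toward smaller (y, x).
Points accepted into a chain are marked visited; after each accepted
leaf a corridor of `consume_width` around the polyline — extended from
the last keypoint to the leaf base (pot rim / reference row) along the
final direction — retires residual seed points so they cannot seed
spurious leaves. Discarded traces (fewer than `min_keypoints = 3`
accepted points) also retire the points they visited; otherwise the
outer loop need not terminate.

Search regions are circles grown from `r0 = 5` px in steps of
`r_step = 5` px up to `r_max` (quarter of the image diagonal by
default). Membership is inclusive (distance ≤ r), and the angle
threshold is inclusive (≤ 20°). Tie-breaks everywhere: smaller
criterion value, then smaller Euclidean distance, then smaller (y, x).

**Direction baseline.** Two seed points from adjacent grid cells can
lie 2–3 px apart, and a chain direction read off such a micro-segment
is numerically meaningless — with ±5 px lateral seed scatter it turns
the angle rules into coin flips and truncates traces mid-leaf. All
direction estimates (turning angles, the arch chord, the half-plane
orientation) are therefore anchored at the most recent keypoint at
least `dir_baseline` behind the chain end; the pipeline sets this to
two sampling-grid cells (2·image_side/40), which keeps the angular
noise from lateral scatter well below the 20° threshold while adding
only a few degrees of lag on realistically curved leaves. The previous
turning angle θ̂ᵢ₋₂ is likewise measured between the smoothed directions
at the last two keypoints; comparing raw segments lets noise ratchet
the reference turn upward until no candidate can pass.

**Random morphology (top view).** The 2nd point is simply the nearest
unvisited point. From the 3rd point on, candidates are restricted to
the axis-aligned half-plane of continued motion (the dominant
coordinate difference picks the axis, ties to horizontal; strict
inequality beyond the current point; a `vector` half-plane mode is
available). The 3rd point minimises the turning angle against the first
chain direction; later points minimise |θ̂ᵢ₋₁(k) − θ̂ᵢ₋₂|. If the best
candidate exceeds 20°, the circle keeps expanding — and whenever no
acceptable candidate exists at the current radius while the circle
already reaches the pot circle, the leaf is complete. Gating the pot
check on an *empty* circle instead deadlocks on straggler points and
eventually hops the trace across the pot onto the opposite leaf (the
two are roughly collinear through the centre), so the check fires on
"no acceptable candidate".

**Regular morphology (front view).** The 2nd point is the one with the
row coordinate closest to the tip's, among the first circle holding at
least two unvisited points. Each later keypoint is first a *tentative*
point: the candidate forming an arch (convex) triple with the chain
behind it at minimal turning angle, the circle expanding until one
exists. It is refined at most once — a candidate near it that lies
strictly above it and stays convex with the confirmed chain replaces it
and is final. The one-shot refinement matters: allowing replacement
chains lets a trace climb an entire neighbouring leaf through repeated
"above and convex" hops, retiring dozens of points while confirming
none. Convexity doubles as the termination criterion: when no convex
continuation exists before the circle reaches the reference line (or
the radius cap), the leaf is complete.

**Arch test.** A triple passes when the middle vertex is on or above
the chord of its neighbours (row coordinates), *or* when the triple is
within 20° of collinear. The chord condition encodes the gravity-arch
shape; the collinearity allowance covers vertical and near-vertical
runs, where a chord-in-x test is ill-posed and a straight chain is
degenerate-convex. The literal per-triple condition as printed (middle
point above both neighbours for every interior index) cannot hold along
a whole leaf and is not used. The convexity invariant guaranteed on
output is the one the tracer enforces: each keypoint forms an arch with
the *baseline-anchored* chain behind it; raw micro-step triples carry
no geometric information either way.

**Consumption corridor.** `consume_width` defaults to 12 px. Residual
seeds of a traced leaf lie anywhere in the eroded ribbon, and the
polyline vertices themselves scatter laterally by up to the ribbon
half-width, so leftover-to-polyline distances reach roughly twice the
eroded half-width (~10–14 px for leaves 12–17 px wide); a 5 px corridor
leaves enough stragglers to seed three-point spurious leaves.

## Phenotypes

Crown width is the maximum pairwise distance between detected tips
(first polyline vertices); under-detected tips shrink it — no
correction is applied. The distribution-consistency rings: `n_rings`
(default 9) circles at equal radial increments strictly between the pot
radius and the crown radius; each ring is intersected exactly with
every polyline segment (tangency counts once, duplicate angles merged
within 1e-9 rad), arcs are the angular gaps times the ring radius, and
rings with fewer than two intersections are skipped with the Gaussian
weights renormalised. The weights are softmax(−(j − N/2)²/2σ²) with
σ = N/4 by default — any positive σ preserves the mid-radius emphasis;
with integer j the argmax lands on round(N/2). Heights in the
height-consistency index are `reference_row − y` and may be negative
for keypoints below the line.

These definitions are exactly translation-invariant and scale-covariant
(lengths as s, variances as s²), verified in the tests on ground-truth
skeletons rendered at two scales; the end-to-end pipeline is only
approximately scale-covariant because the kernel, grid and radii are
fixed in pixels.

## Evaluation

The discrete polyline curvature is the printed interior-angle
second-difference quotient |θᵢ₋₁ + θᵢ₊₁ − 2θᵢ| / (dᵢ₋₁,ᵢ + dᵢ,ᵢ₊₁),
which needs interior angles at i−1, i, i+1 and is therefore evaluated
at vertices 2 … N−3 (0-based). Its magnitude is used for comparability
with the |y″|-based analytic curvature; a signed variant is available.
Note this estimator is a *change-of-turning* measure: it vanishes on
uniformly sampled constant-curvature arcs, so the curvature error on
smooth fixtures is dominated by the analytic term and is nearly
independent of vertex spacing. Ground-truth curves are supplied
analytically by the generator (with a per-leaf mapping from image
coordinates to the curve's abscissa); dense external point lists are
differentiated by moving local quadratic fits. For whole-plant scoring
each predicted polyline is matched to the ground-truth midrib with the
smallest mean vertex-to-midrib distance, and the curvature error is
averaged over matched polylines with at least five vertices.

## Synthetic plants

Top view (default 640 px canvas, pot radius 70 px): leaves radiate from
the pot rim with jittered base angles, quadratic lateral bending
(|curvature| ≤ 0.0012/px at "none" overlap, more at "mild"/"heavy"),
lengths 60–100% of the available radius, base half-widths 6–8.5 px.
The "none" level verifies pairwise-disjoint rendered regions (with
retries, then an error); "mild" permits touching flanks; a speckle mode
adds green background dots to exercise the opening and area filters.
All geometry scales with the canvas so rescaled scenes are similar.

Front view (896 px canvas, 320 px-wide pot): each midrib is a gently
bowed parabolic arc rising from the pot's top row, its apex being the
leaf tip — so the tip is exactly the farthest point from the leaf base,
matching the tracer's initialisation, and every ground-truth triple is
convex. Leaves alternate sides and fan outward (inner ones tall and
near-vertical, outer ones leaning), with a verified ≥ ~10 px clearance
between leaves so the 5×5 closing cannot merge distinct leaves. The
canvas and pot are larger than in top view because a 12-leaf fan needs
that much room to keep inter-leaf clearance above the sampling-cell
scale — below it, no point-connection rule can tell adjacent parallel
blades apart.

Leaf width profiles are strap-like: nearly constant half-width with a
short taper to ~1 px at the tip. The taper deliberately reproduces the
tip-loss phenomenon (erosion deletes the sub-kernel-width tip band, so
traced tips start slightly inward, biasing crown width and leaf length
low by a few percent). This also caps segmentation recovery of
rendered leaf area at ~98.5% on a 640 px canvas.

What passing these tests shows: the selection rules, termination logic
and phenotype formulas behave correctly on clean, moderately noisy
scenes with known geometry. What they do not show: robustness to real
illumination gradients, shadows, specular highlights, background
clutter with leaf-like hues, motion blur, or morphologies outside
gently curved strap leaves (rosettes, compound leaves, heavy mutual
occlusion). Real-image recall should be expected to be lower than the
synthetic 100%.

## Known limitations

- The pot-circle radius inherits the shortest leaf's length; a single
  short spurious contour shrinks it and moves every termination test.
- One leaf can still split into two polylines when a trace dies at a
  large seed gap; the recall metric reports such over-segmentation as
  values above 100% rather than hiding it.
- Phenotypes are in pixels; no camera calibration or mm conversion.
- The regular tracer assumes one convex arch per leaf; S-shaped leaves
  would be truncated at the inflection.
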