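# Methods

## Problem and model

A whole histological cross-section has been cut into four quadrants
(labels ul, ur, ll, lr), each digitized separately. Reassembly estimates a
rigid transform (tx, ty, θ; no scaling or shear) per quadrant in a common
frame. The upper-left quadrant is fixed at the identity, leaving a
9-dimensional search space. Rotation is parameterized about each
quadrant's tissue-mask centroid, which nearly decouples the rotation and
translation coordinates; transforms therefore carry their rotation center
explicitly.

Three properties of the data drive the design: fragments never overlap
(they are cut from one object), tissue is missing along the cuts (the
kerf) and from handling damage, and the cut boundaries do not interlock.
Correspondence must therefore come from tissue *appearance* near the cut
and from *global boundary continuity*, not from contour matching.

## Preprocessing and edge geometry

1. Each fragment image is converted to grayscale (ITU-R 709 luminance),
   rescaled to [0, 1], optionally flipped (user flags correct digitization
   flips), and downsampled so its longest side equals
   `preprocess.target_max_dim` (default 1024 px).
2. Tissue is segmented by Otsu thresholding of the inverted intensities,
   morphological closing (5-px disk), hole filling, and retention of the
   largest connected component. The recipe is exposed in config
   (`segment.closing_radius_px`, `segment.threshold`).
3. The minimum-area rotated bounding box of the mask is computed from the
   convex hull of the foreground pixel squares. One box corner — chosen by
   anatomic label as the corner pointing away from the section center — is
   external to the organ; the boundary-contour points nearest the other
   three corners delimit the two *stitch edges* (one facing a horizontally
   adjacent quadrant, one vertically).
4. Each edge receives a Theil–Sen line: the median of all pairwise slopes,
   intercept the median of `y_i − slope·x_i`. Vertical-facing edges are
   fit with axes swapped to avoid infinite slopes. Edges longer than 500
   pixels are thinned by an even deterministic stride before the O(n²)
   slope enumeration. The line-segment endpoints nearest the organ
   exterior and the section center (`C_out`, `C_in`) feed the misalignment
   term.

Initialization rotates every quadrant so its horizontal-facing edge is
level, joins facing edge midpoints, and pushes overlapping neighbors apart
along the facing normal until pairwise mask overlap is below 1% of the
smaller quadrant. The result is renormalized so ul is exactly the
identity; leveling then holds up to one global rotation (the four
horizontal edges end mutually parallel), which costs nothing because the
stitching cost is invariant under a global rigid motion.

## Cost function

For each of the four adjacent pairs (ul,ur), (ur,lr), (lr,ll), (ll,ul):

- **Dissimilarity.** Edge pixels of both facing edges are mapped to the
  common frame and matched by mutual nearest neighbour with cutoff τ
  (default: the patch radius at the current pyramid level). Each matched
  pair contributes the L1 distance between b-bin intensity histograms of
  p×p patches centered on the pixels (background excluded, histograms
  normalized to probability densities); each unmatched or empty-patch
  pixel contributes the maximum dissimilarity φ (2 for histograms, 1 for
  single intensities). The pair dissimilarity is the mean over the n
  matched plus m unmatched items, so it lies in [0, φ]. Patch size is
  constant in real-world units, so at very coarse levels a patch covers a
  single pixel and raw intensities replace histograms.
- **Misalignment.** `w3·‖C_in¹−C_in²‖ + w4·‖C_out¹−C_out²‖` between the
  transformed best-fit-line endpoints of the facing edges, in
  base-resolution pixels at every level so the weights transfer across
  the hierarchy.

`D_tot` and `M_tot` are the means over the four pairs (a mean rather than
a sum keeps the scale level-independent), combined as
`w1·D_tot + w2·M_tot`. Defaults `w1 = 0.989` (so `w2 = 0.011`),
`w3 = 0.4` (inner) / `w4 = 0.6` (outer), `p = 81`, `b = 16`. Note `w2`
multiplies a quantity measured in pixels while `D_tot` is bounded by 2, so
at working resolution the two terms are comparable for misalignments of a
few tens of pixels.

Patch descriptors depend only on a quadrant's own image, so they are
precomputed once per pyramid level; a candidate evaluation only transforms
coordinates, re-matches (KD-trees), and sums precomputed histogram
distances. Edges are capped at `cost.max_edge_pixels = 200` pixels per
edge (even stride) to bound the matching cost.

## Optimization

An elitist real-coded genetic algorithm: population 20, tournament
selection (k = 3), per-gene uniform blend crossover, Gaussian mutation
with σ = 10% of each bound's half-width, offspring clipped to bounds.
Termination after 25 consecutive generations without a relative
improvement above 1e-4, or 500 generations. Mutation σ is annealed by
×0.85 per stalled generation (floor 5%): full-width mutation while the
search is making progress, fine local refinement once the basin is found.
Without annealing the population converges prematurely about 0.5–1 px
short of the optimum; with it the 9-D sphere test function is solved to
well under 1% of the bound width and synthetic recovery reaches sub-pixel
accuracy.

The hierarchy runs the GA at pyramid factors (8, 2, 1) of the working
resolution. The coarsest level is seeded by the geometric initialization
with bounds of ±25% of the image size and ±20°; each finer level
re-centers a window of ±2·(factor ratio) finer-level pixels — floored at
four coarser-level pixels, the magnitude of the coarser level's residual
error — and ±3° on the upscaled previous solution. All translations are
kept in base-resolution units throughout. The finest level can optionally
run several independently seeded GA restarts ranked by cost
(`finest_restarts`); the fine-resolution cost ranks nearby basins
reliably, whereas coarse-level costs have slightly displaced minima and
are only trusted for a single seeded run. With annealed mutation the
default is a single run.

All randomness flows from one integer seed; two runs with identical
inputs and seed produce byte-identical transform JSON.

## Evaluation measures

- **ASF** — ten fiducials placed automatically on the endpoints and
  midpoints of the four stitch edges of the *reference* reconstruction
  (near-coincident central endpoints merged, outermost points preferred),
  each expressed in both adjacent quadrants' local frames; the error is
  the mean distance between the two legs after mapping through the test
  transforms.
- **MSF** — the same error over externally supplied landmark pairs (for
  synthetic data, generator landmarks straddling each cut; for real data,
  expert-picked correspondences).
- **Hausdorff** — convex hulls of the two composite tissue masks,
  resampled at 1-px arc length, aligned by centroid translation, a 0.5°
  rotation grid search, and golden-section/coordinate-descent refinement
  (0.1-px convergence); the symmetric Hausdorff distance of the aligned
  chains. Symmetric rather than directed distance is minimized.

Each measure is reported in μm and as a percentage of the mean of the
reference reconstruction's width and height, which cancels the physical
pixel scale.

## Synthetic data

`generate_phantom` renders a dark textured ellipse (base intensity 0.45)
on a near-white background (0.97) with bright elliptical blobs emulating
gland lumina (default 8 per 10⁴ px², radii 3–10 px, intensity 0.85–0.95),
plus a smooth large-scale intensity field (±0.12) and fine spatially
correlated noise (σ = 0.06). The large-scale field is what makes patch
histograms informative about position along a cut; the blobs give the
local histogram contrast between gland-dense and gland-sparse regions
that the dissimilarity term exploits.

`fragment_phantom` cuts the phantom with two wavy profiles (amplitude
6 px, two periods) through the tissue centroid, deletes a kerf-wide band
along each cut, optionally removes "bite" disks at fragment boundaries,
crops each quadrant, and applies an independent random rigid perturbation
whose inverse is recorded as ground truth (poses are also kept in the
phantom frame, which makes the kerf-0 reassembly exact to rasterization).
Landmarks (≥ 9 per cut) are sampled on opposite sides of each cut at
`kerf/2 + 2` px from the cut line. Difficulty presets: `easy` (kerf 0,
±5 px, ±3°), `medium` (kerf 5, ±10 px, ±8°), `hard` (kerf 12 + 3 bites,
±20 px, ±15°).

What the phantoms do **not** emulate: staining variation, nonlinear
tissue warping, depth-of-section appearance changes, scanner artifacts,
and fragment scaling. Passing synthetic-recovery tests therefore shows
the geometry, cost, and optimizer are correct and well-conditioned, not
that the appearance model covers all clinical variability. Recorded flip
flags default to off in all presets; when enabled, ground-truth poses
apply to the un-flipped frame and consumers must undo the flip first.

## Problem sizes and observed behavior

Test and validation runs use phantoms of 256 px (module tests, preset
comparisons) and 512 px (pose-recovery runs) with pyramid factors
(4, 2, 1) and (8, 2, 1) respectively; these sizes keep a full stitch in
the 5–30 s range while leaving dozens of pixels of texture along each
edge. On 512-px easy-preset phantoms the pipeline recovers the true poses
to well under 1 px and 0.5°; at 256 px recovery is usually sub-pixel but
occasionally (roughly 1 fixture in 4) settles several pixels away, since
an 81-px patch then spans a third of a quadrant and the histograms lose
locality. Median normalized fiducial errors over five seeds per preset
order strictly easy < medium < hard (roughly 0.3%, 2.6%, 6%): missing
tissue is the dominant error source, mirrored in the over-compensation
failure mode where quadrants are pulled together across a kerf.

## Numerical choices and degenerate inputs

- Bilinear interpolation for intensities, nearest-neighbour for masks;
  `grid-constant` boundary handling so sub-epsilon coordinate excursions
  do not blank border pixels.
- Overlapping quadrants composite in the fixed order ul, ur, ll, lr
  (later wins); any fixed order is acceptable and deterministic.
- Histogram binning uses uniform edges on [0, 1]; intensity 1.0 falls in
  the last bin.
- An all-constant image is a segmentation error; a mask with fewer than 3
  foreground pixels is a geometry error; a kerf that destroys a quadrant
  is a generation error; a canvas too small for a transformed quadrant
  raises a dimension error naming the overflow.
- Ties in mutual-nearest-neighbour matching resolve to the lowest index
  (KD-tree convention), and the double-loop oracle in the tests matches
  this exactly.

## Known limitations

- Rigid transforms only: no scaling or shear, no nonlinear warping.
- The ASF anchor count depends on the merge radius; 10 anchors is the
  default (`eval.n_asf`) but heavily skewed geometries may yield fewer.
- The misalignment weights are in pixel units, so behavior at working
  resolutions far from ~1024 px shifts the balance between the two cost
  terms; `cost.w1` may need retuning at unusual scales.
- Grayscale only; stain-specific color information is deliberately
  discarded.
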