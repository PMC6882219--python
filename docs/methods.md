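# Methods

`oratlas` rebuilds, as a tested pipeline, the workflow behind group atlases
of the optic radiation (OR) and its anterior Meyer's loop (ML): deterministic
streamline tractography per subject, merging of the per-subject bundles in a
common space into a labeled atlas and a tract-density image (TDI), transfer
of the atlas labels into individual spaces through spatial transforms, and
quantitative validation of the labeling. Because the original diffusion
cohorts are not redistributable, everything is exercised on synthetic
phantom cohorts whose ground truth is known exactly; this note records the
models, the parameter choices, and what the phantom experiments do and do
not demonstrate.

## Coordinate conventions

All spatial data live in RAS+ world millimetres (+X right, +Y anterior,
+Z superior). Voxel indices are 0-based; a grid's affine maps voxel
*centers* to world mm. Streamlines are polylines of world-mm vertices.
Label volumes use a fixed legend: 1 = left ORu, 2 = right ORu, 3 = left
ORl, 4 = right ORl (ORu/ORl: upper and lower OR divisions, terminating in
cuneus and lingual cortex respectively).

## The phantom cohort

A phantom bundle must exercise every feature that makes the OR hard to
track: a sharp angle where the bundle leaves the lateral geniculate nucleus
(LGN), fanning, an anterior hairpin (Meyer's loop) around the temporal
horn, and the twisting arrangement of the two divisions.

Each streamline is a shape-preserving (PCHIP) spline through control
points: LGN seed point, a 5-mm optic-tract-like stub rotated `sharp_angle`
(default 75 deg) from the initial loop heading, five knots on a circular
arc of radius `loop_radius_mm` (default 12 mm) around a "temporal horn"
center, a mid-return point, and a division-specific cortical target.
Key properties:

* **Exact anterior envelope.** PCHIP does not overshoot local extrema at
  knots, and the fanning perturbs the loop radially *inward* only (one
  streamline per division is pinned to the envelope), so with zero jitter
  the bundle's maximal Y is exactly `loop_apex_y`. The default template
  places the temporal-tip landmark 25 mm anterior to the apex: true dTM
  (temporal tip to anterior ML ridge, along Y) = 25 mm per side.
* **Twist.** A lateral offset of `twist_gain/2` (default 2 mm) with
  opposite signs for ORu/ORl, modulated by `tanh((y_c - y)/8)` with the
  crossover `y_c` at -15 mm, makes the ORu start medial to the ORl and end
  slightly lateral, crossing exactly once. The offset is tapered to zero
  within ~3 mm of the LGN so streamlines still begin at the seed.
* **Fanning.** One angular/radial draw per streamline, shared by both
  divisions and both sides (sides are exact mirrors about X = 0), with
  spread `fan_half_angle` (default 12 deg) as seen from the LGN.
* **Noise.** Per-point Gaussian jitter (`jitter_sd`, default 0.3 mm),
  ramped in over the first 3 mm of arc length.
* **Loop radius.** 12 mm was chosen so that the per-step tangent rotation
  at the stock step size (0.5 mm) stays below ~2.5 deg; anatomical hairpin
  radii are tighter, but a coarser grid (1.5 mm voxels, matching the
  source data's resolution) cannot represent a much tighter trackable
  hairpin anyway. This is the main idealization of the phantom.

A cohort is the template bundle pushed through per-subject random
diffeomorphic transforms: an affine (rotation <= 3 deg/axis about the grid
center, anisotropic scale within +/-4%, translation <= 3 mm/axis) plus a
Gaussian-smoothed displacement field (correlation length 15 mm, peak
2 mm, smoothstep-tapered to zero at the grid border, positive Jacobian
verified). Landmarks (LGN center, temporal tip, true apex) travel through
the same transform, giving per-subject ground truth. Defaults were fixed
once as plausible inter-subject anatomical variability at template scale.

The phantom emulates geometry, not physics: there is no diffusion signal,
no ODF reconstruction, one orientation peak per voxel, and no crossing
tracts. Passing tests therefore demonstrate the correctness of the
tracking/atlas/validation machinery on OR-like geometry, not robustness to
the noise and fiber-crossing ambiguity of real diffusion MRI.

## Orientation fields and tracking

Rasterizing a bundle yields, per traversed voxel, the normalized mean of
sign-aligned segment directions and a QA (quantitative-anisotropy stand-in)
equal to the streamline traversal count scaled to a maximum of 1.

The tracker is the stock deterministic ("streamlined") algorithm: angular
threshold 90 deg, step 0.5 mm (the printed step size interpreted as mm),
smoothing 0.8, length bounds [30, 300] mm, 50,000 seeds drawn uniformly
over the seed-mask volume with random sub-voxel positions, bidirectional
tracking with trilinear interpolation. Vector interpolation sign-aligns
each corner vector to the incoming direction (antipodal symmetry). The
direction update is

    d_next = normalize((1 - smoothing) * d_prev + smoothing * d_field)

i.e. **smoothing weights the interpolated field direction** and the
previous direction contributes the complementary 0.2 as inertia. The
opposite reading (0.8 inertia) is provably untrackable on curved bundles:
on a circular field of radius r the direction lags the tangent by a steady
angle ~4x the per-step field rotation and the track drifts outward by
`step * sin(lag)` per step with no restoring force — 20 mm of outward
spiral on a 12-mm circle — so no parameter setting would carry a track
around Meyer's loop. The semantics are documented here and configurable.

The QA termination threshold is exposed as a parameter (the original
protocol chose it by visual inspection). `auto_qa_threshold` provides a
stand-in heuristic: the smallest threshold keeping >= 99% of suprathreshold
QA mass inside a tissue mask. Phantom runs use 0.001 (QA is normalized by
the maximum count, which occurs at the LGN funnel where all streamlines
converge, so bundle-body QA is small).

Seeding counts *seeds*, not retained streamlines; a 50,000-seed run on the
phantom retains roughly 18,000 streamlines after ROI and length filtering
and recovers >= 90% of the true bundle's voxels.

## Atlas construction

Per-subject tracked streamlines are filtered by division-specific target
ROIs (the seed-ROI combinations that define ORu and ORl), carried to the
template space through the inverse of the subject's ground-truth transform,
and merged with subject/division/side tags preserved. Voxel labels: a voxel
receives a division's label when streamlines of that division from at least
`min_subject_support` subjects (default 1) traverse it; overlaps go to the
division with more subject support, exact ties to the upper division
(lower label value). TDI: each streamline increments every voxel it
traverses by exactly one (set semantics per streamline), with traversal
computed exactly by slicing segments at half-integer plane crossings in
voxel coordinates. Label volumes are never interpolated — any resampling
is nearest-neighbor.

Rigid mask registration (for final atlas-space transfer) aligns mask
centroids and principal inertia axes (choosing among the four proper sign
combinations by overlap), then polishes with a Nelder-Mead search of
rotation and translation against a lightly blurred target mask; the blur
turns the piecewise-constant overlap into a smooth objective. Masks with
<= 3 voxels or near-isotropic inertia are rejected.

## Spatial transforms

A transform is `T(p) = A p + D(A p)` with an invertible affine `A` and an
optional displacement field `D` (trilinear, zero outside its grid).
Label resampling uses the pull-back convention: the transform handed to
`resample_labels` maps target-space points into the source space, and each
target voxel center takes the nearest source label. Inversion: the affine
exactly; the field by fixed-point iteration `E <- -D(z + E)` to 0.005 mm,
sampled on a grid twice as fine as the forward field's (the refinement
keeps the inverse field's own interpolation error below the 0.05-mm
round-trip budget). Composition is exact for affines and sampled on a grid
when fields are involved.

A practical note on nearest-neighbor round trips: pulling labels onto a
grid of the *same* resolution and back loses ~1-2% of boundary voxels to
rounding residue, independent of warp amplitude. Labeling onto a finer
individual-space grid (1 mm against the 1.5 mm atlas grid — the realistic
arrangement, since anatomical T1 grids are finer than diffusion grids)
keeps the back-projected lookup error below half an atlas voxel and makes
the round trip exact in practice.

## Validation statistics

* **Correspondence rate (CR).** Within the middle third of a side's
  anterior-posterior extent (the anatomically simple body of the OR), the
  maximal-tract-density voxels are collected per coronal slice (ties
  included; a global top-fraction variant is available), and CR is the
  fraction of them falling inside the side's labels. The per-slice rule
  makes CR insensitive to absolute density; whether the original procedure
  used per-slice or global maxima is not documented, so both exist with
  per-slice as default.
* **Shift tolerance ("cyber intervals").** Labels are translated laterally
  in one-voxel steps (configurable in mm); CR is recomputed at each offset.
  The tolerable CR is, per direction, the CR at the largest offset at which
  the max-density voxels still touch the shifted labels; it is flagged as
  undefined when no intersection/non-intersection transition occurs within
  the scanned range. The full profile is always reported.
* **Bootstrap.** Percentile CI of the mean CR over 10,000 resamples with
  replacement at 95% confidence, with the observed-mean-inside-CI flag.
  The flag is nearly always true by construction; the CI itself is the
  informative output and both are reported.
* **Safety zone.** The label mask dilated by Euclidean distance (default
  5 mm, world units, via a distance transform); the check passes when all
  max-density voxels lie inside — the clinically relevant criterion when
  CR drops under mislocalization.
* **Sample size.** Smallest n >= 2 whose two-sided one-sample t-test at
  level alpha reaches the requested power, by exact noncentral-t
  computation (tail probabilities via the survival function and the
  noncentrality symmetry; the naive CDF difference underflows to NaN at
  small df). With the stock inputs — tested-CR mean 75%, tolerable-CR mean
  4%, SD 10%, alpha 0.05, power 0.90 — the answer is 3, cross-checked in
  the tests against Monte-Carlo simulation and statsmodels.

## Anatomical measures

The anterior ridge is the maximal-Y point of the side's ML portion
(anterior to the LGN coronal plane), ties broken toward the midline. dTM
is the Y-difference between the temporal-tip landmark and the ridge — the
surgical "distance behind the temporal pole" convention; a Euclidean
option exists. The twist profile emits, per 3-mm Y slab, the signed
lateral difference of division centroids (positive = ORu lateral), with a
0.25-mm dead band against centroid noise when counting crossings.
Landmarks are explicit inputs; no segmentation or parcellation is
attempted.

## I/O and export

Volumes are NIfTI-1; displacement fields 4-D NIfTI (last dim 3, mm);
affines plain-text 4x4; streamlines TCK (world RAS+ mm, matching the
internal representation bit-for-bit) with tags in a JSON sidecar, plus a
plain-text dialect for fixtures. The DICOM export writes one secondary-
capture-style file per slice with the labels burned into the 12-bit pixel
range at a configurable intensity, geometry tags (LPS+) reproducing the
NIfTI affine to < 1e-3 mm, and UIDs derived deterministically from a seed.
DICOM-SEG is out of scope.

## Problem sizes

The shipped experiments use a 1.5-mm grid of 70 x 77 x 41 voxels, 150
streamlines per division and side, 10-subject cohorts, 2,000 tracking
seeds per subject and side for atlas building, and the full 50,000-seed
budget for the tracker-recall experiment; these sizes were chosen so a
complete study runs in minutes on one CPU while every statistic operates
in its intended regime.

## Known limitations

* Single orientation peak per voxel; no crossing-fiber decoding.
* Transforms are generated, never estimated from images; the original
  segmentation-driven inverse normalization is out of scope, so accuracy
  statements concern label *propagation*, not registration quality.
* The tracker's inertial smoothing biases tracks toward the inside of
  tight curves by a sub-millimetre margin; at the phantom's loop radius
  this is absorbed by the bundle thickness.
* The bootstrap "mean inside own CI" test is reported as specified even
  though it is uninformative relative to the CI itself.
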