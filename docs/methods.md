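# Methods

## Problem and model

In MRgFUS thalamotomy for essential tremor, a thermal lesion is placed in
the ventral intermediate nucleus (Vim). Because the Vim is invisible on
structural MRI, tract-based analysis asks which part of the
dentatorubrothalamic tract (DRTT) the lesion actually transected. This
package implements the downstream analysis: bundle decomposition, overlap
scoring, outcome scoring, and predictor selection. Everything upstream —
tractography, lesion segmentation, thalamic parcellation, nonlinear
registration — is an *input* (TCK tractograms, NIfTI masks and label
volumes, affine/warp files), not something this package estimates.

## Streamline geometry

Streamlines are ordered 3-D point lists in RAS mm. Distances use the
minimum average direct-flip (MDF) metric: both streamlines are resampled
to `k` points and the mean point-wise Euclidean distance is taken,
minimised over reversing one of them (streamlines have no canonical
orientation). `k = 12` by default — the long-standing convention for this
family of clustering algorithms; the metric is insensitive to `k` once
the tract's curvature is resolved. MDF is symmetric, non-negative and
flip-invariant, and rigid transforms are isometries for it (tested).

Resampling is piecewise-linear along the polyline with one deliberate
refinement: the linear pass is **iterated to the fixed point at which
consecutive chord lengths are equal** (convergence below 1e-9 mm,
typically 10–30 iterations). A single pass equalises arc length along the
*input* polyline but not the chord lengths of the *output*, which makes
the operation non-idempotent (re-resampling moves points by ~0.1 mm).
The fixed-point form is exactly idempotent and keeps endpoints exact; it
cuts corners by at most a few hundredths of a millimetre at the point
counts used here, far below the jitter scale of any tractogram.

## Bundle clustering

`QuickBundles` is the classic single-pass incremental algorithm: each
streamline (resampled, flip-aligned) joins the nearest cluster centroid
by MDF if the distance is under the threshold, else founds a new cluster;
centroids are running means of flip-aligned members. The pass is
order-dependent by construction; streamlines are processed in stored
order and tests that depend on exact clusters fix that order.

The anterior/middle/posterior decomposition replaces the visual
inspection a human rater would do with a reproducible rule:

* the threshold is searched upward (default 2 mm start, 1 mm step, 30 mm
  cap) until a decomposition **qualifies**: ≥ 3 clusters each holding
  ≥ 5 % of streamlines (`min_fraction`) *and* the three largest of those
  jointly holding ≥ 90 % (`min_coverage`). The coverage requirement is
  essential: without it the search halts while the tract is still
  fragmented into many partial clusters and role labels become
  arbitrary (observed directly on pooled multi-subject data);
* the three clusters are role-labelled by the rank of the mean
  anterior-axis (+y) coordinate of their centroid points restricted to
  the middle third of the centroid (the mid-tract slab), because the
  sub-bundles converge at their endpoints and would dilute the ranking.

"Most coherent" is defined as smallest mean MDF distance to all other
streamlines in the bundle, computed exactly (O(n²), blocked and
vectorised; ~13 s for 3,000 streamlines). It is deterministic and
brute-force checkable; ties break by original index. Cluster-confidence
style alternatives would weight neighbours by distance but need their own
bandwidth parameter.

## Overlap metrics

Transection overlap samples each streamline at an arc-length step of half
the smallest voxel edge (default) and counts the streamline as transected
if any sample's nearest voxel (round-half-away-from-zero per index, fixed
for bit-reproducibility) is nonzero in the binary ablation mask. Sample
points outside the grid are ignored. Point sampling is monotone: halving
the step never decreases the count (tested). Exact segment–voxel
traversal would remove the step parameter but not change any conclusion
at 1 mm grids and sub-millimetre steps.

Label overlap multiplies the hard segmentation with the mask: for each
label, volume = voxel count where both agree × voxel volume
(|det| of the 3×3 affine block). Because hard segmentations partition the
grid, per-label overlaps plus the background overlap sum exactly to the
ablation volume (tested). Grids must share shape and affine; resampling
between spaces is the caller's responsibility, and space agreement is
asserted through explicit `space_id` tags rather than header forensics.

## Clinical scores

CRST parts A/B/C are accepted as part totals (item-level CRST entry is
out of scope); the combined score is their sum, capped at the scale
maximum of 160 by validation. The Hand Tremor Score sums eight 0–4
upper-limb items for the dominant hand (rest, postural, action, pouring,
handwriting, large/small constrained spirals, constrained straight
lines) and seven for the non-dominant hand (no handwriting): maxima 32
and 28. Percent change is `100·(pre − post)/pre`, positive on
improvement; a zero pre-treatment score makes the change undefined and
the record is flagged and excluded from that response downstream. When a
subject has several follow-ups the latest dated post-treatment record is
used (ties resolve to the last in row order).

Skull parameters (SDR, skull thickness, inner/outer skull angle) arrive
as arrays of exactly 1,024 values — one per transducer element — and are
summarised as mean and sample SD (ddof = 1; unspecified in the source
material, fixed here for reproducibility; at n = 1,024 the choice is
numerically irrelevant).

## Regression

`ols_fit` is ordinary least squares with intercept (statsmodels under
the hood), reporting raw coefficients, standardized coefficients
(β̂·sd(x)/sd(y); p-values are invariant to that rescaling), R² and RSS.
Forward selection adds, at each step, the candidate whose coefficient
t-test p-value in the current model is smallest and below α = 0.05; ties
break by larger |t|, then pool order, so selection is deterministic. The
two-stage procedure runs selection over patient-specific variables first,
then over treatment-specific variables with the first stage locked in,
and compares the nested models with the F test on residual sums of
squares. No multiple-testing correction is applied across responses,
matching the analysis this mirrors. Standardized coefficients are the
primary effect-size report (the magnitudes of published βs are consistent
with standardization); raw-scale coefficients are always emitted
alongside. Secondary-lesion exclusion is a row filter, not special-cased
logic.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* the analysis
assumes, not anatomy:

* **Bundles** are cubic-spline arcs (a C-shaped dentate→thalamus-like
  course in the x–z plane) with sub-bundle offsets of −6/0/+6 mm along
  the anterior axis, a per-streamline Gaussian lateral offset
  (SD = `jitter_sd`, default 1 mm) and per-point jitter (SD/3). Offsets
  sit on the anterior axis so that role ranking is identifiable by
  construction.
* **Lesions** are voxelised spheres; **nuclei** are Voronoi partitions
  (hard segmentation by construction). Real lesion cores are
  ellipsoidal and real nuclei have smooth boundaries; nothing in the
  overlap arithmetic depends on that.
* **Cohorts** default to the studied conditions: n = 31 subjects, age
  75.72 ± 7.20 y, bundle overlaps with the means/SDs reported for the
  native/anterior/middle/posterior bundles, ablation volume
  11.61 ± 4.82 mm³, 9 of 31 subjects flagged with secondary lesions, and
  a response built as Σβᵢzᵢ + ε on sample-standardized posterior overlap
  (+0.533), age (−0.375) and SDR element-array SD (−0.324), with ε tuned
  so the true three-predictor model has R² ≈ 0.548, then rescaled to a
  percent-change scale (44.77 ± 16.6) and clipped to [−100, 100]. The
  generative truth (standardized effects and the exact raw-scale
  coefficient map) is returned for recovery tests; with zero residual
  noise the raw map is recovered to machine precision.

Passing tests on these data demonstrate algorithmic correctness and
statistical calibration under the assumed model — independent Gaussian
predictors, linear effects, homoscedastic noise. They do not demonstrate
robustness to the correlated predictors, non-linear dose–response or
heteroscedastic outcomes of real cohorts.

At n = 31 with these effect sizes, joint recovery of all three predictors
by forward selection has measured power of roughly 55 % when the pool
contains the three effect variables, and materially less through the
two-stage path (the stage-1 residual still contains the large treatment
effect); recovered standardized coefficients are selection-inflated for
the smaller effects, with absolute bias well under 0.1. These are
properties of the design, not implementation artifacts.

## Numerical choices and degenerate inputs

* Resampling: fixed-point iteration tolerance 1e-9 mm, cap 100
  iterations; zero-length streamlines resample to repeated points.
* Voxel membership: round half away from zero on each index.
* Displacement fields are sampled trilinearly; points outside the field
  domain raise (naming the streamline) rather than extrapolate, because
  silent extrapolation corrupts overlap scores.
* Label volumes must be integer-valued; floats that are exactly integral
  are accepted and cast, anything else is rejected.
* Affine mismatch tolerance for overlap grids: 1e-4.
* Cluster-search failure raises with the full (threshold, cluster-count)
  trajectory to make the failure diagnosable.
* All generators are pure functions of (spec, seed); pipeline reruns with
  identical config and seed produce byte-identical CSV/JSON outputs.

## Problem sizes in the test suite

Tests run the full stated conditions where they are cheap (3,000→1,000
coherence filtering, 200 recovery replicates at n = 31, 500 null-ANOVA
replicates) and reduced sizes where only the property matters (e.g.
30-replicate sign-pattern checks, 10-replicate R² calibration at
n = 10,000). The whole suite completes in about a minute on one CPU.

## Known limitations

* QuickBundles order dependence is inherited deliberately; permuting
  input can change cluster identity near the threshold boundary.
* Transection counting is point-sampling, not exact segment traversal;
  counts near a mask boundary can differ within the documented 2 % band
  under re-gridding.
* The role-labelling slab and coverage parameters are heuristics tuned
  for geometrically separable sub-bundles; tracts without dominant
  three-cluster structure correctly fail the search rather than being
  forced into roles.
* TCK is the only tractogram dialect (float32, mm); TRK/VTK are out of
  scope, as is estimating the nonlinear warps applied by
  `transform_tractogram`.
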