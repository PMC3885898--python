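# Methods

## Model and procedure

`hemiconn` analyses hemispheric asymmetry of a structural connectome built
from streamline tractography.  The analysed object is, per subject, a
symmetric nonnegative matrix `A` over `N = 90` ROIs (45 homologous pairs;
labels 1..45 left, 46..90 right, homolog = id + 45).  Entry `A_ij` starts as
the number of streamlines with one terminal point inside ROI `i` and the
other inside ROI `j`.  Streamlines with a terminal point in background (or
off-grid) are discarded; streamlines starting and ending in the same ROI are
kept on the diagonal but excluded from link analysis.  Raw counts are then
corrected for acquisition bias toward large, nearby regions
(connection-density correction):

    w_ij = 2 / (S_i + S_j) * Σ_f 1 / ℓ_f ,

where `S_i` is the exposed voxel-face surface area of ROI `i` (mm²), and
`ℓ_f` the polyline arc length (mm) of each kept streamline of the link.  The
literature states this correction only as "inversely proportional to the sum
of the linked ROI surfaces and fiber length"; the explicit form above is the
standard one and satisfies both stated proportionalities (doubling both
surfaces halves every weight; weights are linear in streamline count at
fixed lengths).

Asymmetry is quantified by the asymmetry index

    AI = (R − L) / ((R + L) / 2) ∈ [−2, 2],

negative meaning leftward dominance.  Two unit types are analysed across a
cohort:

* **ROI asymmetry** — `L` and `R` are the strengths of a homologous ROI
  pair: the sum of the ROI's link weights over *all* other ROIs (ipsilateral
  and contralateral), excluding only the self-link and the link to the ROI's
  own contralateral homolog.
* **Link asymmetry** — `L` and `R` are the weights of a homologous pair of
  intra-hemispheric links (side-free pair indices 1..45).  Inter-hemispheric
  links are excluded by construction; ROIs flagged non-supratentorial in the
  ROI table (e.g. cerebellar) are excluded entirely.  A link is "tracked" in
  a subject iff `L + R > 0`; units tracked in fewer than
  `ceil(presence_fraction * n_subjects)` subjects are dropped (default
  fraction 0.75, i.e. 13 of 17 subjects).

Each unit's per-subject AI sample is tested against zero with a two-tailed
one-sample t-test, `t = mean / (sd / √n)`, `df = n − 1`,
`p = 2 P(T_df ≥ |t|)`.  Subjects with `L = R = 0` contribute no AI for that
unit (the index is undefined) and the df shrinks accordingly; units left
with fewer than two usable subjects, or with zero sample variance around a
nonzero mean, are flagged `untestable` rather than silently dropped.  A
degenerate sample that is identically zero is reported as `t = 0, p = 1`
(it is exactly the null).  Reported p values are uncorrected for multiple
comparisons, matching the analysis this package models; a Benjamini–Hochberg
column (`p_fdr_bh`) is emitted alongside as a clearly labelled extension.

## Tractography

FACT propagation: from a seed at each masked voxel center, the streamline
advances by `step_size` along the principal eigenvector of the voxel
containing the current point (nearest-voxel lookup, no interpolation), with
the eigenvector sign chosen to minimise the angular change.  Propagation is
bidirectional, the two halves joined at the seed.  A streamline terminates
when the next point would leave the mask or when the turning angle between
successive steps exceeds `angle_threshold_deg` (default 45°); streamlines
shorter than `min_length` are discarded.  The output therefore satisfies two
contracts checked in the tests: every emitted point lies inside the mask,
and every interior turning angle is ≤ the threshold.

On an ideal circular arc of radius `r` traversed with chord steps of length
`s`, successive directions turn by exactly `2·asin(s/(2r))`; propagation is
admissible under the threshold iff that turn is ≤ 45°.  In a voxelised
tangent field the realised per-step turn additionally reflects nearest-voxel
quantisation, and tangential stepping drifts slowly outward (per-step radial
drift ≈ `s²/2r`), so completion of long arcs additionally requires the step
to be small relative to the tube width.  The tests check the closed form on
exact chord geometry, and empirically that fine steps track arcs within the
angle contract while steps implying a turn > 45° terminate immediately.

The spline filter fits an interpolating spline (cubic where the point count
allows) parameterised by cumulative chordal arc length and resamples it at a
fixed step, preserving both endpoints exactly.  On the tracker's output
domain — polylines with interior turns ≤ 45° — resampling at twice the step
size never increases arc length (verified numerically over random bounded-
turning polylines).  For arbitrarily sharp zig-zags an interpolating spline
can overshoot corners and lengthen the path; such inputs do not occur
downstream of the tracker and the filter makes no claim about them.

## Coordinate conventions and numerical choices

* Voxel `i` owns `[i, i+1)` along its axis; the voxel center is `i + 0.5`;
  world mm = `affine @ voxel`.  Endpoint-to-voxel mapping is the floor of
  the inverse-affine coordinate; a coordinate exactly on the far boundary of
  the grid belongs to the last voxel (single stated tie-break, tested).
* ROI surface = exposed voxel-face area from the label map (faces whose
  6-neighbour has a different label or lies off-grid), not a reconstructed
  mesh: deterministic, resolution-honest, and checkable against brute-force
  face enumeration.
* Default tracking step is 0.5 × the smallest voxel dimension (below the
  voxel Nyquist spacing); default `min_length` is 10 mm for brain-scale
  grids, overridden to a few mm on small phantom grids where tubes are
  short.
* All TSV output uses a pinned float format so that identical inputs
  (including the seed) reproduce byte-identical files; this is asserted by
  an end-to-end double-run test.
* Eigenvectors inside the tracking mask must be unit-norm (validated, error
  otherwise); a gray-matter probability hook zeroes parcel labels at voxels
  with probability ≤ 0.5, mirroring atlas ∩ gray-matter intersection with a
  "greater than 50 %" rule.

## The phantom generator

The synthetic cohort emulates the study design the analysis targets: 17
subjects, 90 ROIs in 45 mirror-symmetric homologous pairs, and white-matter
bundles linking ROI pairs.  ROIs are cubic blocks on a lattice in the left
half of the grid, mirrored exactly across the mid-sagittal plane (grid
center along axis 0).  Bundles are straight or circular-arc tubes between
block centers; the tensor-field surrogate sets each tube voxel's eigenvector
to the tangent of the nearest centerline point, and errors on overlapping
tubes whose tangents disagree by more than 30°.

Asymmetry is injected on streamline **counts**, the generative quantity
behind the raw link weight: a target AI of `δ` for a link draws expected
counts `base·(1 − δ/2)` left and `base·(1 + δ/2)` right, so the noise-free
count AI is exactly `δ`.  Between-subject variability is multiplicative
lognormal noise (log-scale SD `subject_noise_sd`, default 0.1) applied
independently per side before rounding — nonnegative and right-skewed, as
count noise plausibly is; the modelled study reports no per-subject variance
figures, so this default is a convention, not an estimate.  Right-hemisphere
streamline geometries are exact mirror images of their left counterparts
drawn from a shared pool, so a cohort with `δ = 0` and zero noise is
perfectly symmetric *through the surface/length correction*: count-level AI
is exactly 0 and corrected-weight AI is zero to floating-point roundoff
(≤ 1e−12).  A stray fraction (default 10 %) of streamlines with at least one
background endpoint exercises the discard rule in every fixture.
Generation is deterministic given `(rng_seed, subject_index)`.

What the phantom does **not** emulate: diffusion signal formation (no
b-values, no Rician noise), crossing fibers, registration error,
gyral/sulcal geometry, or realistic ROI shapes and adjacency.  Passing tests
therefore demonstrate the correctness of the counting, correction, and
inference machinery under known ground truth — not tractography accuracy on
real brains.

## Bundle centroid paths

For visualization, each link's bundle is reduced to one polyline: all
streamlines are oriented canonically (lower ROI id first when a label volume
is available; otherwise a lexicographic/nearest-endpoint geometric rule with
the same reversal invariance), resampled to `n_sections` points equally
spaced in arc length (default 20; the modelled analysis states no section
count), and section `k`'s centroid is the mean of the `k`-th points.  The
construction is invariant to reversing any input streamline and equivariant
under rigid transforms, both tested.  It is a deterministic, documented
stand-in for centroid-of-sections bundle summaries used for anatomical
display; it performs no clustering and is intended for visualization only.

## Problem sizes used in checks

The packaged checks run on deliberately small instances chosen as the
smallest sizes that exercise every rule: 90-ROI cohorts on a 24×15×12 grid
with 23 bundles for structural contracts; 4-ROI phantoms with one bundle for
recovery (20 replicate cohorts of 17 subjects); count-level 40-ROI cohorts
totalling ≥ 1000 unit tests for type-I calibration; tracking oracles on
fields of ≤ 10³ voxels.

## Known limitations

* The presence rule treats a unit as tracked when either side is nonzero
  (`L + R > 0`), the weakest condition under which AI is defined; whether
  one-sided links should instead be zero-filled or dropped is ambiguous in
  the modelled analysis and is left as a documented choice.
* Whether ROI surfaces should be measured on the atlas-space ROI or the
  gray-matter-intersected ROI is likewise unstated; the intersected label
  map as delivered is used.
* The sign convention is AI = (R−L)/mean with negative = leftward, matching
  the tabulated statistics of the modelled analysis; one of its figure
  captions states the opposite reading, a contradiction documented here and
  not resolved.
* FACT is deterministic by design; no probabilistic tractography, tensor
  fitting, or registration is provided.
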