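# Methods

`morphowrap` compares 3D morphologies of organisms that offer few or no
anatomical landmarks.  Instead of matching features, it imposes
correspondence by construction: a 2D grid of explicitly numbered points
is adjusted to each specimen and projected onto its surface, so grid id
*i* samples the homologous surface location on every individual.  All
downstream statistics are dense per-id fields.

## Pipeline model

**Extract.**  An intensity stack (e.g. confocal, with anisotropic voxel
spacing) is Gaussian-smoothed with an isotropic physical bandwidth
(default σ = 5 µm, converted per axis to voxel units), trilinearly
resampled to an isotropic lattice (default 15 µm cube) and triangulated
at a user-chosen intensity threshold with the standard lookup-table
marching-cubes algorithm (scikit-image).  The threshold is a required
parameter: signal intensity varies per stack and choosing it is a
judgement call, not something the package estimates.  Boundary handling
for the blur is reflective so specimens are not dimmed at stack edges;
this also conserves total intensity.  Optional uniform Laplacian
smoothing (unweighted 1-ring average) is limited in practice to 1–3
passes, because each pass shrinks the mesh; the package warns beyond 3.

**Wrap.**  The template grid (default 400 × 320 = 128,000 points,
row-major ids) is adjusted to each specimen either by an exact 2D
thin-plate-spline interpolant through named landmark pairs, or by a
deformation cage bound to the grid with 2D mean-value coordinates.
Both routes have linear precision — an affine correspondence is
reproduced exactly — and agree with each other on affine motions, which
is tested.  The adjusted grid is projected onto the mesh by parallel
rays along z; where a ray crosses the mesh several times the *maximum*
z intersection is kept (the outermost surface toward the viewer, the
side the scan actually imaged).  Rays that miss the mesh mark their
grid id invalid.  The projection preserves the warped grid's (x, y)
coordinates exactly.

**Superimpose.**  Casts are aligned by least-squares superimposition
over translations and proper rotations (partial Procrustes; SVD
solution with the reflection branch excluded, since all specimens are
same-handed half bodies).  Size is deliberately retained by default —
for ecological morphotypes size is signal, not nuisance — giving *form*
differences; enabling the uniform scale gives size-adjusted *shape*
differences.  The fit is estimated on the intersection of valid ids of
the two point sets and then applied to all valid points; there is no
nearest-neighbour matching anywhere, so missing regions simply drop out
of the analysis.  Groups are star-aligned to a single prototype cast
(default: the first reference-group specimen) rather than by iterative
generalised Procrustes; this matches the prototype-based workflow the
package reproduces and keeps the alignment order-independent.

**Compute.**  Group mean models average coordinates id-wise over ids
valid in *every* member, so each retained id averages the same number
of specimens.  The displacement field superimposes one mean model onto
the other and subtracts coordinates; magnitudes are Euclidean norms in
µm.  Every id valid in all casts of both groups is tested per axis with
a two-sided Mann–Whitney/Wilcoxon rank-sum test: exact null
distribution (computed by the classical partition recurrence) for
tie-free samples with combined n ≤ 25, otherwise a normal approximation
with tie and continuity correction.  Multiple testing is corrected per
axis with Storey q-values: π₀(λ) = #{p > λ}/(m(1−λ)) on the grid λ = 0,
0.01, …, 0.95, smoothed by a cubic polynomial, evaluated at λ = 0.95
and clipped to [1/m, 1]; q-values follow the step-up rule.  With π₀
forced to 1 the procedure reduces exactly to Benjamini–Hochberg, which
is tested.

**Ellipsoids.**  Per tested id each group contributes an axis-aligned
ellipsoid centred at the group mean with per-axis 95 % CI half-widths
of the mean as radii (t-quantile · s/√n; an `observation` variant using
t · s is available — the two differ only by the √n factor).  Overlap of
two axis-aligned ellipsoids is decided exactly: quick accept when either
centre lies inside the other, quick reject on disjoint per-axis slabs,
otherwise the second quadratic form is minimised over the first
ellipsoid via the scalar Lagrange-multiplier equation (coordinates
decouple for axis-aligned forms), bisected to 1e-12; touching counts as
overlap, and zero radii collapse axes to the segment/disc/point cases.
Non-overlap is rendered black (localised group difference), overlap
purple.  The permutation validation exchanges ⌊fraction · min(n_A,
n_B)⌋ randomly chosen casts between the groups (sizes preserved,
default fraction 0.5, 3 permutations) and recomputes the map; a genuine
group effect should dissolve into near-complete overlap.

### A note on null behaviour of the overlap map

For two groups drawn from the same population, the per-id probability
that the two mean-CI ellipsoids fail to overlap is *not* ≈ 0: in the
spherical case non-overlap is the event ‖Δ‖ > r_A + r_B, where Δ
accumulates variance over three axes while the radii are per-axis
half-widths.  For n = 10 vs 9 at 95 % this intrinsic rate is ≈ 1.5–2 %
independent of the noise scale, and spatially correlated variation
clusters the affected ids.  A pure-null overlap map therefore shows a
few percent black, and permuted maps of a real effect are "almost all",
not perfectly, purple.  This is a property of the statistic, not a bug;
tests assert levels consistent with it.

## The synthetic study

The generator emulates the study design the workflow targets: two
groups of bilaterally halved, smooth, convex-ish mm-scale bodies.  The
body is the upper half of a superellipsoid (defaults: length 2500 µm
antero-posteriorly, height 1600 µm dorso-ventrally, lateral half-width
400 µm, exponent 4 for the flat-topped carapace-like silhouette) with a
tapered posterior tail spine (500 µm) and a smooth head bump, defined
as a single-valued height field z(x, y) — so parallel z-projection is
unambiguous by construction.  The template grid covers the carapace
region (silhouette fills ≈ 96 % of the grid box); the protruding spine
itself lies outside the grid and its elongation appears as
posterior-margin displacement.

The treated ideal is the control ideal under a group effect chosen to
mirror a predator-induction experiment in which **size is the dominant
response**: a global 1.1× scale about the cast centroid, a posterior
drag of up to 75 µm confined to the rear 30 % of the body semi-length
(the carapace following a 1.3× spine elongation, quadratic ramp), and
one 20 µm lateral head-region bump (σ = 150 µm).  The resulting
noiseless displacement field (the *truth*, defined after the partial
Procrustes fit, matching the headline analysis) has a median of ≈ 75 µm
and peripheral values of 100–160 µm, the magnitude range the method is
meant to resolve; after the size-adjusted fit the median collapses by
an order of magnitude, reproducing the qualitative size-dominance
finding.

Individual variation is a smooth stationary random field per axis
(random-phase superposition of 40 plane-wave cosines, wavelengths
300–1500 µm, sd 5 µm — biological variation is spatially coherent, so
i.i.d. jitter alone would make neighbouring rank tests unrealistically
independent) plus i.i.d. fine jitter of sd 2 µm representing
meshing/projection roughness.  Every cast is finally displaced by a
random rigid motion (≤ 15°, ≤ 300 µm) so the superimposition stage does
real work.  Everything is a pure function of the seed.

What passing tests show — and what they do not: the generator's casts
share the template's validity pattern exactly (the grid follows the
specimen, so no points are lost at silhouette differences), its noise
is Gaussian-ish and stationary, and its effect is known in closed form.
Real cLSM data additionally carry stitching artefacts, staining
inhomogeneity, non-stationary variance (the real defended group was
visibly more variable) and landmark-placement error, none of which are
modelled.  Tests therefore validate the *machinery* — geometry,
alignment, test calibration, FDR behaviour, overlap logic — not the
biology of any particular organism.

Because the exact rank-sum test at 10 vs 9 is discrete, its attainable
level just below p = 0.01 is 0.762 %; null studies reproduce that
fraction (not 1.000 %), and the calibration check averages over
replicate null studies and uses the empirical between-replicate
standard error, which is the appropriate error scale under spatially
correlated variation.

## Numerical choices

- Shrink-wrap intersections use per-triangle barycentric tests on
  binned grid points (relative tolerance 1e-9, edge hits deduplicated
  by the max-z reduction); triangles with vanishing (x, y) area
  (vertical walls) cannot carry a graph surface and are skipped.
- Procrustes uses the SVD with the smallest singular direction's sign
  flipped when needed to enforce det(R) = +1; degenerate (collinear,
  zero-variance) configurations are rejected.
- Ellipsoid bisection runs to 1e-12 with a 1e-9 tangency tolerance.
- TPS smoothing defaults to 0 (exact interpolation); collinear
  landmark sets are rejected at construction.
- Marching-cubes input is resampled so lattice node i sits at physical
  position i · cube_size, making vertex coordinates exact µm.
- Fixture/simulation sizes used by the test-suite and the acceptance
  script: 200 × 160 grid (32,000 ids) for the end-to-end study, 60 × 48
  for unit-level studies, six replicate null studies.  These are the
  package's standard desk-scale settings; the full 400 × 320 grid is
  the production default.

## Known limitations

- The wrap stage assumes the surface is single-valued along z over the
  grid (true for the scanned outer half of a bilaterally symmetric
  animal); overhangs would silently record only the outermost sheet.
- Star alignment to one prototype inherits the prototype's
  peculiarities; the prototype should be a representative specimen.
- Confidence ellipsoids are axis-aligned in the common aligned frame;
  correlated per-point variation (a rotated covariance) is not
  captured, and per-id CIs are not corrected for the number of ids.
- The q-value π₀ smoother is the cubic-polynomial default; with very
  few tests (m < 10) it is refused rather than guessed.
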