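# Methods

This note records how each stage is defined, which defaults were chosen
where the field's practice leaves the choice open, and what the synthetic
validation does and does not demonstrate.

## Image model and containers

A scan is a 3D integer grid (`GrayscaleVolume`) with an isotropic voxel
edge in µm (default 18.2 µm, a common intact-core scan resolution) and a
bit depth of 8 or 16.  Segmentations are co-registered label volumes
(`PhaseMask`) over {pore, solid, stone, POM, root, excluded}; `excluded`
marks voxels removed from every denominator so that all fractions are
reported on a stone-free basis.

## Preprocessing

Fixed order: background removal → 3D median → contrast stretch → ROI crop.

**Background removal.**  A trivariate polynomial of total degree 3 is
least-squares fitted to the intensities and subtracted.  Coordinates are
normalized to [−1, 1] per axis (raw voxel indices make the degree-3 normal
equations ill-conditioned), and the fit runs on a regular decimated
sub-grid capped at 200 000 samples — a smooth field needs no more; the
stride used is logged.  The residual is returned to the original
brightness scale by an affine map of unit slope (restoring the global
mean).  A min–max stretch was rejected: when the fit explains nearly all
variation the residual is quantization noise, and stretching it to the
original range amplifies that noise to full scale.  Note that a global
polynomial also absorbs whatever degree-≤3 component the *true* structure
has; shading removal is only meaningful when structure is fine-grained
relative to the trend, which holds for real cores and for the validation
phantoms.

**Median filter.**  Cube neighborhood of half-width 2 (5×5×5), reflected
edges.  "Radius in all directions" is read as the Chebyshev ball (cube);
the cube is also what common plugin implementations use.  The filter's
known side effect is curvature-driven erosion of small convex pores
(~6.6/r² relative volume loss for a pore of radius r voxels — measured on
digitized spheres); see *Validation phantoms* below.

**Contrast enhancement.**  Linear stretch saturating 0.6% of voxels by
default, split evenly between tails.  Per-tail clip count is
`floor(pct/2 · N)`; the cut intensities are order statistics, ties at a
cut are all treated alike, so the mapping is deterministic and
order-free, and monotone non-decreasing everywhere.

**ROI crop.**  Centered or offset sub-volume; the offset is recorded in
the volume's metadata so subsamples can be audited for disjointness.

## Solid/pore segmentation

Two grayscale thresholds split voxels into certain pore (< t_low),
certain solid (> t_high) and an ambiguous band resolved spatially: each
ambiguous voxel takes the phase with the larger inverse-distance-weighted
sum of already-classified voxels within a Chebyshev window (half-width 2
by default), iterated — with the window growing by one whenever an
iteration decides nothing — until no voxel remains.  Pore wins ties.
This keeps the structure of indicator-kriging segmentation (certain
tails, locally resolved ambiguity) while being deterministic and exactly
reproducible by a brute-force vote, which the tests exploit.

**Automatic thresholds.**  When not supplied, the band is centered at the
midpoint of the two class means of the Otsu partition, with half-width
0.5 × the pooled within-class standard deviation.  Centering at the Otsu
threshold itself was rejected after measurement: with tight modes and
very unequal class sizes (15% pore), Otsu sits at the edge of the pore
mode and a band centered there swallows the entire pore class (6–8%
misclassification on noise-free phantoms); the class-mean midpoint is
stable in exactly those conditions.

**Stones.**  Bright voxels above `stone_t` (default: midpoint of t_high
and the intensity maximum) are grouped with 26-connectivity; components
strictly larger than 10 mm³ are stones, smaller bright specks return to
solid.  `stone_free_basis` relabels stones as excluded; every downstream
fraction divides by (total − excluded) voxels.

## Pore metrics

**Porosities.**  Total porosity is 1 − ρ_bulk/ρ_particle (ρ_particle
default 2.6 g cm⁻³); visible porosity is the stone-free pore fraction;
sub-resolution porosity is the difference.

**Interfacial area.**  Marching-cubes isosurface area of the binary pore
phase multiplied by a fixed calibration constant **0.92**.  Raw
marching-cubes area on binary digitized spheres overestimates 4πr² by a
stable +8.5–9.2% across radii 8–30 voxels; dividing by 1.087 puts
digitized spheres within 0.6% for r ≥ 10.  The constant was fixed once
from that sphere calibration and is covered by a regression test.  Like
any isotropic calibration it trades accuracy on axis-aligned flat faces
(~8% underestimate) for accuracy on curved interfaces, which dominate
soil pore walls.  Both absolute area (mm²) and area per stone-free volume
(mm²/mm³) are reported, since the normalizing volume is otherwise
ambiguous.

**Euler number.**  Standard 3D configuration formula, 26-connected
foreground (`skimage.measure.euler_number`).

**Connectivity.**  26-connected pore components; a component counts as
connected if any voxel lies on any external face.  Reported as connected
pore volume / total pore volume.

**Pore-size distribution.**  Local size of a pore voxel = radius of the
largest discrete ball `{d : |d|² ≤ r²}` fully contained in pore space
that covers it, computed by the two-distance-transform construction
(erosion centers via the squared EDT, coverage via an EDT from the
centers), sweeping integer radii from large to small.  This is exactly
morphological opening by balls of decreasing radius, and the tests assert
voxel-for-voxel equality with a brute-force opening oracle that
materializes the structuring elements.  Integer squared distances avoid
float comparisons at sphere rims.  Boundary convention: pore space is
assumed to continue past the volume faces and inscribed balls may extend
beyond them (thin ROIs would otherwise be edge-penalized); balls must be
anchored inside the volume.  Voxels too small to host a radius-1 ball are
binned at half a voxel radius.  Bins default to multiples of the voxel
size; fractions are per stone-free voxel, so the distribution sums
exactly to the visible porosity.  Named presets cover the radius ranges
commonly aggregated in soil studies (30–50, 30–70, 30–90, 30–100, 15–58,
87–150 µm).

One property worth stating: the *per-voxel* local radius is monotone
under dilation of the pore phase (opening is monotone in the set), but
the *volume-weighted mean* radius is not — dilating a field of many tiny
pores plus one large pore grows the small-pore mass much faster and can
lower the mean.  The tests check the per-voxel form.

## POM

**Band calibration.**  From marked representative fragments: the band is
(mean of per-fragment minima, mean of per-fragment maxima).  Averaging
across fragments tames single-fragment extremes.

**Segmentation.**  Band threshold → opening (`open_steps` erosions then
dilations with the 6-connected radius-1 ball; default 2, exposed as a
parameter since practice varies) → Gaussian smoothing of the binary field
(σ = 1 voxel) re-thresholded at 0.5 → 26-connected components →
components strictly greater than 0.018 mm³ kept.  Fragments are sorted by
volume descending (centroid lexicographic order breaks ties) and
re-labelled 1..n; the label volume is kept alongside the fragment table
because shells, matching and root distances need voxel identity.

**Loss.**  loss% = (1 − A_a/A_b) × 100, with A_b and A_a percent of the
same reference count — the stone-free voxel count of the before ROI — so
the statistic is a pure voxel-count ratio immune to denominator drift.
Matching across co-registered scans is greedy nearest-centroid with a
0.5 mm cap; a before-fragment with no partner is reported as 100% loss
(`unmatched_after`), an after-only fragment with NaN loss
(`unmatched_before`) — never dropped.

**Shells.**  For distances 1, 5, 8 mm: layer = voxels with Euclidean
distance to the fragment in (0, d], excluding the fragment and excluded
voxels; fraction = pore voxels in layer / layer voxels.  Layers are
nested by construction.  For fragments near the volume boundary the
reported truncation fraction is the share of the ideal (unbounded-grid)
layer lying outside the volume, computed on a padded grid; this is only
evaluated when a fragment actually sits within the largest shell distance
of a face, because the padding is memory-heavy at fine resolutions.
With a local-thickness map, shell fractions can be restricted to pore
radius classes (inclusive bounds).

**Root distances.**  Minimum over fragment voxels of the EDT of the root
phase, in mm.  An empty root mask yields undefined (`None`) distances,
not infinities.

## Validation phantoms

`standard_core_spec` builds the package's standard validation core:
spheres of radius 12–22 voxels plus through-going channels of radius 9–14
voxels at ~16% visible porosity (128³–160³ grids), solid matrix at mean
160, pores at 60, noise sd 8 (8-bit), and a multiplicative degree-3
shading field of ±4% amplitude — the residual shadowing scale of
cone-beam scanners.  Porosity sits in the intact-topsoil range, and the
pore radii put the phantom at the packing-void/biopore scale that carries
most image-resolved porosity.  The radii are also the regime where the
fixed 5³ median is nearly volume-neutral: its curvature erosion scales as
~1/r², so a phantom dominated by resolution-scale pores would be
systematically under-segmented by any implementation of this chain —
that is a property of the published procedure, not of this code.

`pom_study_spec` builds the decomposition study: 20 fragments of 0.35 mm³
(≈0.9 mm across, the sharp-edged size class paired-scan studies track)
grown by stochastic 6-neighbor dilation (acceptance probability 0.85,
giving irregular but not fractal boundaries) in a solid matrix at 40 µm
voxels.  Decomposition peels prescribed voxel fractions from the fragment
surface inward, ties within a peeling round broken by the seeded RNG, and
re-renders removed voxels at pore intensity.  Losses are drawn uniformly
from [0, 0.8].  Fragment size matters here too: the cleaning steps shave
a roughly constant surface shell, so the loss ratio is nearly unbiased
for these fragments (regression slope ~0.95, RMSE ~3.5 pp) but degrades
for fragments within a factor ~3 of the 0.018 mm³ cutoff.

Seed discipline: the phantom's `seed` drives only noise; `structure_seed`
drives stochastic geometry (blob growth).  Identical specs give identical
volumes, and changing `seed` never changes the ground-truth labels.

**What the phantoms do not emulate:** beam hardening, ring artifacts,
partial-volume blur at phase boundaries, registration error between
paired scans, spatially correlated noise, or POM grayscale overlap with
wet aggregates.  Passing tests therefore demonstrate correctness of the
measurement chain under the stated image model, not robustness to every
scanner artifact; the ROI-cropping stage exists precisely because rings
are avoided, not corrected.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; pipeline outputs are byte-identical for fixed config + seed.
- Squared EDTs are rounded to integers before comparisons (exact for
  voxel grids).
- `enhance_contrast` on a constant volume warns and returns the input;
  empty pore phases yield zero metrics, except connectivity, which is an
  error (0/0); an all-excluded mask is an error.
- Thresholds are validated against the bit-depth range; `t_low > t_high`
  is rejected everywhere.
- Voxel size always comes from configuration, never TIFF tags; a
  resolution tag that disagrees by >1% triggers a warning.

## Problem sizes

The shipped tests and the acceptance script run the study conditions at
48³–160³ (segmentation recovery at 128³, loss recovery at 160³/40 µm,
oracle checks at ≤ 128³).  These sizes were chosen so the full validation
executes in a few minutes on one CPU while every phantom keeps the stated
porosity, fragment-size and noise conditions; all thresholds are checked
unchanged at these sizes.

## Known limitations

- The voted-band segmentation approximates indicator kriging's spatial
  resolution of ambiguity but does not solve kriging systems; on scans
  whose ambiguous band contains structured texture (rather than boundary
  blend), results will differ from a true kriging implementation.
- The interfacial-area calibration is isotropic-curvature-oriented; flat
  axis-aligned interfaces are underestimated by ~8%.
- Multiplicative shading is corrected by an additive fit; the residual
  (phase contrast × shading amplitude) is negligible at ±4% shading but
  grows linearly with shading strength, and the contrast stretch amplifies
  whatever remains.
- Fragment matching is centroid-based and assumes co-registered pairs; it
  will mis-pair fragments that move more than 0.5 mm or split into
  comparable pieces.
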