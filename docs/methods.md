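# Methods

`ctmorph` implements the analysis half of a micro-CT morphometry workflow for
small teleost fish: given a greyscale volume of a contrast-stained specimen
and a labelled reference atlas, it produces a per-organ segmentation by label
propagation and a set of comparative morphometric measurements.  Because the
real scan volumes the method was developed on are not redistributable, the
package ships a synthetic phantom generator with exact ground-truth labels;
all quantitative validation in the test suite and in
`scripts/acceptance.py` runs against that ground truth.

## Conventions

All grids are indexed `(z, y, x)` with z the antero-posterior axis and the
anterior end at low z; physical units are micrometres, coordinates are
0-based and boxes half-open.  Transforms map fixed-frame physical points to
moving-frame points (the pull-back convention), so resampling the moving
image onto the fixed grid is a single pass, and the chain that aligns a
specimen to the atlas is directly the chain that carries atlas labels onto
the specimen grid.

## Whole-body mask and QC

The body mask is the largest 26-connected component of the above-Otsu
voxels after binary closing with a ball of radius 3 voxels, followed by
filling of enclosed cavities.  The filling step matters: the eye lenses
image as low-absorption ("water-like") regions *inside* the body, and both
lens detection and cross-section profiling require the mask to be the whole
body, cavities included.  The Otsu threshold maximises the between-class
variance of the two-class split `{<= t, > t}` with ties broken toward the
smallest t; on histograms with an empty gap between modes the criterion is
flat across the gap, so the tie-break is applied within a 1e-12 relative
tolerance of the maximum to keep the result deterministic.

QC reports rather than excludes: completeness (body not touching the axial
faces of the volume), histogram agreement with a reference (Bhattacharyya
distance, default threshold 0.2 — the original exclusion rules are not
quantified anywhere, so the statistic and threshold are this package's
choice and are configurable), and an optional two-sample z statistic on
tissue intensities (flagged above |z| = 1.96).  Exclusion decisions belong
to the caller.

## Landmarks

Lens detection operationalises "spherical, water-like, enclosed": candidate
regions are 26-connected components of below-threshold voxels inside the
body mask, gated by Wadell sphericity (default >= 0.85) and a minimum size
(default 100 voxels); among the survivors the pair minimising the volume
self-similarity score |Vi - Vj| / (Vi + Vj) is taken as the lenses, with
ties broken by the larger sphericity sum and a hard error when the tie
survives.  Left and right are assigned by y centroid (a documented
convention; nothing downstream depends on it).  The tail landmark is the
centroid of the body-mask voxels in the posterior 30% of the mask's axial
extent.  The three landmarks determine a similarity transform (Umeyama
closed form — rotation, isotropic scale, translation) used to initialise
registration; solving for scale here is deliberate, since specimens differ
in size and the registration stages then start from a size-matched guess.

On a noise-free synthetic volume whose background is exactly zero the
below-Otsu class can collapse to the empty set (the threshold sits at the
edge of an empty histogram gap); alignment then falls back to a
moments-based initialisation (centroid + volume-ratio scale) with a
warning.  Real scans, and the phantoms under their default 2% noise, do not
hit this case.

## Registration

The similarity metric is the mean squared intensity difference; atlas and
specimen share a contrast mechanism, so SSD is adequate and cheap (the
metric is isolated behind one function should a correlation-based metric be
needed).  Each stage runs over a Gaussian pyramid; a level's sigma (voxels)
smooths both images before decimation.  Levels printed with 0 iterations
are skipped, and pyramid factors are clamped per volume so no level drops
below ~6 voxels per axis — whole-body schedules stay usable on small organ
bounding boxes.

*Rigid/affine*: an affine correction, centred on the fixed volume and
pre-composed with the running chain, is optimised by L-BFGS with an
analytic gradient (image gradient sampled at the mapped points, chain rule
through the correction parameters).  Translation parameters are rescaled by
one tenth of the mean physical extent to balance the parameter space.  The
optimiser's relative-improvement stop is the schedule's `stop_epsilon`
(default 1e-6), and a level's result is only accepted when it does not
increase that level's metric.

*Diffeomorphic*: a demons scheme — normalised force
`-r grad(w) / (|grad w|^2 + r^2/K)` with `K` the mean squared voxel
spacing, additive updates, Gaussian regularisation of the field with the
level's sigma (floored at 0.5 voxels so the finest level is never
unregularised), early stop on `stop_epsilon` relative improvement, and
reversion of any update that increases the metric.  After every level the
field is checked for a positive Jacobian determinant of `id + u` at all
grid points and shrunk by 0.8 (with a warning) until positive — fields
returned by the package are always diffeomorphic in this discrete sense.

Two schedule sets ship: the full-resolution schedules (whole-body pyramid
12/8/4/2 at 1000/500/250/0 iterations, sigmas 4/3/2/1; organ-level
rigid/affine 12/8/4/2 at 1000/500/250/100 and diffeomorphic 10/6/4/2/1 with
sigmas 5/3/2/1/0) and reduced desk-scale schedules (factors 4/2, tens to
hundreds of iterations) sized for the ~160-voxel phantoms used throughout
the tests.  The organ diffeomorphic schedule defines five levels but only
four printed iteration counts; this package continues the halving pattern
with 125 at the finest level, configurably.  Schedules serialise to JSON
(`ctmorph/data/fullres_schedules.json` carries the full-resolution set).

## Atlas segmentation

Whole-body alignment registers the binary body masks (landmark similarity
init, then rigid -> affine -> diffeomorphic).  A binary mask determines the
axial position of a slowly tapering body only to about a voxel; this is
accepted because every organ is subsequently re-registered on intensities
inside its own bounding box (atlas label mapped through the chain, axis-
aligned box plus a 10% margin per axis), which restores sub-voxel accuracy
where it matters.  The atlas side of the sub-volume registration is cropped
to the image of the specimen box (plus padding) so per-organ work scales
with the organ, not the body.

A sub-volume registration is declared divergent when its final SSD both
exceeds the initial SSD by more than 10% and remains above 10% of the
sub-volume's intensity variance; the second condition prevents flagging
already-converged cases where interpolation noise dominates an SSD near
zero.  Propagated labels are cleaned (largest component, radius-1 opening
and closing, hole filling; changes above 10% of the voxel count warn), and
per-organ results are assembled into one full-frame label map with overlap
conflicts resolved toward the organ with the lower final metric
(deterministic; ties fall to the lower organ id).

## Morphometrics

Organ volume is voxel count times voxel volume.  Surface areas come from a
marching-cubes isosurface of the binary mask after a 0.6-voxel Gaussian
smoothing: raw marching cubes on binary data measures the staircase
(about +8% on a digitised ball), heavier smoothing rounds corners away
(a cube loses ~9% at sigma 1).  Sigma 0.6 was validated against analytic
solids: digitised balls of radius 8–12 voxels measure within ~2% of
4 pi r^2 and a 20-voxel cube's Wadell sphericity comes out 0.85 against the
analytic 0.806 (within the documented +-0.05 estimator tolerance).  The
same smoothing is used for slice perimeters (traced 0.5-level contours), so
a digital square measures close to 4s (circularity within 0.03 of pi/4) and
a digital disc's circularity lands around 0.95 — circularity of digitised
circles is reported with a +-0.08 tolerance.

Cross-section profiles are per-slice areas (pixel count times pixel area —
so the identity `sum(area_z) * dz == mask volume` is exact by construction)
and circularities `4 pi A / P^2`, with positions expressed as percent of
the mask's axial extent.  Group statistics resample every profile to a
common 100-point percent grid by linear interpolation.

Normalisation to the specimen's total volume follows dimensional
consistency: volumes by `V_tot`, areas by `V_tot^(2/3)`, lengths by
`V_tot^(1/3)`, making all normalised quantities invariant under isotropic
rescaling.  The group profile carries both raw (µm²) and normalised areas;
`head_region_mean` — the quantity behind the head-region strain contrast —
is computed on the normalised areas, since comparative morphometrics of
animals with life-long growth must be independent of absolute body size
(the normalised statistic is also exactly immune to the per-specimen size
jitter in synthetic cohorts).  Note that under this normalisation a head
whose raw cross-section is scaled by a factor s reads as a smaller
contrast than `1 - s`, because the shrunken head also lowers `V_tot`; the
head-contrast strain preset accounts for this (see below).  The raw-area
counterpart is reported alongside.

## Shape analysis

Organ masks are aligned by centroid translation and rotation of the
principal axis (largest eigenvector of the second-moment tensor) onto z,
with the heavier mass half placed anterior; nearly isotropic shapes
(relative eigenvalue gap < 1%) are translated only, with a warning.
Probability maps are voxel-wise means of the aligned binary masks (values
exact multiples of 1/n); consensus shapes threshold at p >= 0.60 with an
inclusive boundary ("60% and higher").  Surface distances are unsigned
nearest-vertex distances between marching-cubes surfaces, reported in both
directions plus the symmetric mean, since the two directions genuinely
differ for nested or elongated shape pairs.  Dice of two empty masks is
defined as 1.0.

## The phantom generator

The phantom is a tapered elliptical body along z containing two lens
spheres (symmetric about the mid-sagittal plane, anterior ~18% of body
length), a brain ellipsoid, a spinal-cord cylinder and a gut tube, with
intensity ordering lens (30) < background (0 outside the body) < muscle
(120, plus smooth texture of amplitude 10) < gut (160) < brain (180) <
spinal cord (200) on an arbitrary 0–200 absorption scale, and Gaussian
noise of sd 4 (~2% of the dynamic range) by default.  Placing the lens
intensity below the whole-body Otsu threshold makes the lens detector
exercise the same logic it would on stained scans.  Label maps are the
analytic geometry on the voxel grid, pre-noise, so lens volumes, inter-eye
distances and cross-section areas have closed-form expectations.

Ground-truth deformations compose a similarity perturbation with a random
Gaussian-smoothed displacement field normalised to a requested peak
magnitude; generation fails (rather than silently folding space) if the
field's Jacobian is not safely positive.  Cohorts apply a strain preset
(head cross-section area factor, brain volume factor, lens radius and
inter-eye distance factors) and per-specimen individual variation:
similarity jitter (rotation <= 2 deg, scale +-2%, translation <= 2 voxels),
a small smooth local field (<= 2 voxels), intensity gain jitter (sd 2%) and
fresh noise, all scaled by a single `variation_scale` knob (0 = identical
twins).  The head preset applies its full area factor up to 32% of body
length and ramps back to 1 by 50%, so the anterior-30% window used in the
head-region statistic is uniformly scaled.  The shipped head-contrast
preset uses a raw anterior-area factor of 0.705, calibrated once on the
analytic phantom geometry so that the volume-normalised head-region
statistic — the size-invariant form in which strain contrasts are compared — shows a
20% reduction against the reference strain.  Every random draw descends
from one seed through a documented `(seed, specimen index, stage)`
hierarchy.

What the phantom does *not* emulate: reconstruction artefacts (rings, beam
hardening), skeletal microstructure, anisotropic organ texture, stain
gradients, and genuinely non-diffeomorphic anatomy differences.  Passing
the suite therefore demonstrates the correctness of the geometry, the
registration machinery and the statistics under realistic noise and smooth
deformation — not robustness to every artefact of real scans.

## Validation problem sizes

The acceptance computations use 160 x 96 x 96 phantoms: five deformed
specimens (local fields up to 8 voxels, similarity jitter, 2% noise) for
segmentation fidelity, two cohorts of five for the head-region contrast,
and twenty seeded similarity ground truths (rotation <= 15 deg, scale
0.9–1.1, translation <= 10 voxels) at 96 x 64 x 64 for parameter recovery.
These sizes were chosen so the full suite validates every stage in minutes
on a single CPU while keeping each organ tens of voxels across; the
schedules for full-resolution scans ship alongside and slot in by changing
`schedule_set` to `"fullres"`.

## Known limitations

- SSD assumes a shared contrast mechanism; cross-stain or cross-modality
  registration needs a different metric.
- Whole-body mask registration bounds axial accuracy at ~1 voxel; organs
  not re-registered locally inherit that bound.
- The demons field is regularised per level but not constrained to a
  stationary-velocity parameterisation; inverse fields are not provided.
- Surface-distance maps use nearest-vertex distances, not point
  correspondences; they localise divergence but do not define a mapping.
- Label refinement (largest component + radius-1 morphology) assumes
  organs are single compact bodies; it is inappropriate for fragmented
  structures.
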