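# Methods

## Problem and scope

The package segments a single liver tumor in 3D from contrast-enhanced
CT, given a presegmented binary liver mask and one seed voxel near the
tumor center on an axial slice. It targets hypo-intense lesions
(darker than the surrounding parenchyma), which dominate in
contrast-enhanced portal-phase CT; hyper-intense lesions are out of
scope, as are liver segmentation itself, multi-tumor extraction in one
pass, and DICOM series handling.

## Coordinate conventions

Arrays are indexed `data[i, j, k]` with i along x, j along y, k along
z; axial slices fix k, coronal fix j, sagittal fix i. Voxel centers
map to physical space as `origin + index * spacing`, and every
millimetre rule (20 mm centroid stop, 15 mm VOI margin, surface
distances) is computed through the spacing. Region masks are {0, 1};
the {0, 128, 255} encoding exists only in the seed-label mask consumed
by the graph construction.

## Preprocessing

Non-liver voxels are replaced by a constant +200 HU — above any liver
or lesion intensity, so region growing cannot leak out of the liver
and the fill never attracts the lesion cluster. The volume is median
filtered (3×3×3, edge-replicated) and resampled to 1 mm isotropic
voxels by trilinear interpolation (nearest-neighbor for masks); the
output grid has `round(size·spacing/t)` voxels per axis, so resampling
at the native spacing is the identity. Seed correction then finds the
minimum-intensity voxel in a 5×5×3 box (x, y, z) around the seed *on
the isotropic grid*; the z-thin box mirrors the thick-slice geometry
of the original acquisition. Ties keep the original seed if it is
among the minima, otherwise the smallest (k, j, i) wins — the
correction must be deterministic to serve its purpose of removing
operator variability. Median filtering precedes resampling; the two
nearly commute on piecewise-smooth CT, and filtering at native
resolution is cheaper.

## VOI extraction (CCRG sweep)

Confidence-connected region growing runs in 2D on each of the three
orthogonal slices through the seed, with 4-connectivity and an initial
disk of radius 2 pixels. Each iteration recomputes the region mean and
standard deviation and admits all frontier pixels within
m_c ± l·σ_c. A σ floor of 1 HU keeps the inclusion range non-degenerate
on constant regions (noiseless phantoms). Per plane, the factor l
sweeps {1.5, 1.75, 2.0, 2.25, 2.5}; a plane's sweep stops — dropping
the offending mask and all larger l — when the region reaches 80 % of
the liver area on that slice (growth has flooded the parenchyma) or
its centroid drifts more than 20 mm from the seed (growth escaped the
lesion). The surviving masks are summed and thresholded at half the
maximum vote (inclusive). The bounding box unions the axial (x, y),
coronal (x, z) and sagittal (y, z) extents, padded by
`round(15 mm / spacing)` voxels per axis and clipped at the grid.

## KFCMS

The clustering alternates four vectorized steps until the largest
center movement is below 0.01 HU (cap 100 iterations): kernel
memberships from the Gaussian-kernel distance; the spatial function
h (box sum of memberships over the (2r+1)³ neighborhood, border-
clipped, computed in 3D since the VOI is volumetric); the refinement
u′ ∝ u^p h^q; and the kernel-weighted center update. Exact
center hits receive crisp membership (the formula's limit) instead of
a division by zero. Defaults: N_c = 2 (lesion, liver), m_f = 2, p = q
= 1, r = 1, σ_f = the standard deviation of the VOI intensities
(scale-adaptive). With p=1, q=0, r=0 and large σ_f the scheme reduces
to standard fuzzy C-means behavior, which the tests exercise.

Initialization inside the pipeline is seed-informed: the lesion center
starts at the corrected seed intensity (by construction the darkest
voxel near the click) and the liver center at the median intensity of
liver voxels in the VOI. A quantile-based start was considered but
discarded: a small lesion contributes only a few percent of the VOI's
voxels, so low percentiles land in the parenchyma's noise tail and
both clusters converge onto liver/fill modes. The generic
`kfcms_fit` entry point keeps percentile (or seeded random)
initialization for standalone use on balanced data. The lesion cluster
is the one whose center is nearest the seed intensity; remaining
clusters pool into the background map, so P_fg + P_bkg = 1.

## Graph cuts

Nodes are the VOI voxels plus two terminals (sink = foreground seeds,
source = background); n-links connect 6-neighbors. Region capacities
follow the probability maps, with hard seeds pinned by an effectively
infinite capacity, realized as `1 + Σ(all finite capacities)` so no
minimum cut can sever a seed link. The boundary capacity between
neighbors v, u is

    B = ((I_v − I_u)² + 1)^(−1) + λ·I_sg   (default, "additive")

with I_sg the sigmoid of the spacing-aware gradient magnitude averaged
over the two endpoints. The sigmoid width α_s is negative (default
−10), so strong edges map to I_sg ≈ 0 and are cheap to cut; β_s
defaults to the 90th percentile of the gradient magnitude, placing the
transition at the VOI's strongest edges. A multiplicative variant
`B = ((I_v−I_u)²+1)^(−1) · (1+λ·I_sg)^(−1)` is selectable via
`boundary_model`; both satisfy the solver-vs-enumeration equivalence
tests. γ (n-link weight) defaults to 1.0 and λ to 0.5. Probabilities
are used directly as capacities rather than negative log-likelihoods.
The min-cut is computed with igraph's s-t mincut (C core, float
capacities); tests verify its cut value against exhaustive enumeration
on grids with up to 14 unknown voxels and against an independent
energy evaluation of the returned labeling.

## Postprocessing

The 26-connected component containing the seed is kept (falling back
to the nearest component within 3 voxels when the cut excludes the
seed voxel itself); a 3×3×3 binary median removes protrusions, and a
radius-1 ball dilation counteracts the min-cut's preference for short
boundaries, which otherwise biases the result toward slight
undersegmentation. The mask is finally resampled to the original CT
grid by nearest neighbor (linear interpolation would produce
non-binary values).

## Evaluation and scoring

Border voxels (mask voxels with a face-neighbor outside; the grid edge
counts as outside) define the surfaces; distances use a Euclidean
distance transform with the voxel spacing as sampling, and the
symmetric statistics are aggregated per direction before combining so
the result is bitwise symmetric in (A, B). The 0–100 score is
`max(0, 100 − 10·|m|/ref)` — the unique linear rule that awards 100 at
zero error and 90 at the manual-quality reference (VOE 12.94 %, RVD
9.64 %, ASD 0.40 mm, RMSD 0.72 mm, MaxD 4.0 mm). |m| makes over- and
undersegmentation penalize RVD equally. The overall score averages the
five error metrics; DICE is reported alongside but not scored, and the
identity VOE/100 = 1 − DICE/(2 − DICE) is enforced as a property test.

## Phantom generator

Phantoms place a liver ellipsoid (~100 HU) in a bright background
(+200 HU, matching the preprocessing fill), carve hypo-intense
ellipsoidal lesions, blur the piecewise-constant scene with a Gaussian
(boundary partial-volume effect), and add white Gaussian noise.
Default spacing (0.7, 0.7, 2.0) mm exercises anisotropy and
resampling; grids of 128×112×40 voxels keep a full pipeline run at a
few seconds. Difficulty grades: *easy* — 60+ HU contrast, ≤ 1 mm blur,
lesions 10–30 mm; *medium* — 40 HU contrast, 1.5–2 mm blur; *hard* —
≤ 20 HU contrast, ≥ 3 mm blur, including a lesion tangent to the liver
border. Ground truth is the unblurred ellipsoid set and is independent
of the noise seed.

What the phantoms do **not** emulate: parenchymal and lesion texture,
vessels and bile ducts, rim enhancement, necrotic cores, neighboring
organs, beam-hardening or motion artifacts. Passing the phantom suite
therefore demonstrates the pipeline's correctness and its behavior
under contrast/noise/blur degradation, not clinical-grade accuracy on
real CT, where heterogeneous lesions and weak boundaries are harsher
than anything generated here.

## Numerical and degenerate-case choices

- CCRG σ floor 1 HU; integration threshold inclusive (≥ max/2).
- KFCMS: exact-hit crisp membership; collapsed initial centers are
  respread over the intensity range; non-convergence returns the last
  iterate with a recorded warning.
- Graph: only strictly positive capacities become edges; the reported
  cut value equals the labeling energy within 1e-9.
- Determinism: every stage is deterministic given the configuration;
  stage timings are recorded in the run report only on request
  (`--timings`) so that default reports — and masks — are byte-identical
  across reruns.

## Known limitations

Hyper-intense (arterial-phase) tumors violate the darkest-voxel seed
correction and the hypo-intense cluster selection. Lesions abutting
previously resected margins or the liver border inherit background
hard seeds from the mask boundary, which can truncate the cut. Very
small lesions (< 5 mm) occupy one or two slices and give CCRG too few
pixels for stable statistics. The dilation radius trades a positive
volume bias (RVD of order +10–20 % on 10–20 mm lesions) against
undersegmentation of blurred boundaries.
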