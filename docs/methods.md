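# Methods

`prostasm` implements a hybrid segmentation strategy for the prostate gland
in T2-weighted MR volumes: a volumetric CNN (or any pluggable initializer)
produces a rough binary segmentation, and a statistical shape + appearance
model — an active shape model (ASM) built from corresponded surface vertices
of a training cohort — refines the boundary under shape-plausibility
constraints. This note records the model, its assumptions, the defaults, and
the numerical choices, so that a reader can judge what the synthetic
experiments do and do not demonstrate.

## Image model and preprocessing

The observed image is modelled as `v = u · f + n`: an uncorrupted image `u`,
a smooth positive multiplicative bias field `f`, and additive noise `n`.
Bias correction is delegated to the N4 algorithm (SimpleITK), with a
foreground mask from Otsu thresholding, the field estimated on a 4× shrunk
copy over 4 fitting levels (50 iterations each), reconstructed on the full
grid from the log field, normalized to unit mean inside the mask, and
divided out. N4 is established prior art; the in-repo contract is
behavioural (a known low-order polynomial field in [0.8, 1.2] must lose at
least half of its coefficient of variation; a field-free image must change
by under 1% median).

Because MR intensities have no absolute scale, volumes are standardized by
piecewise-linear histogram mapping in the Nyúl–Udupa style: landmarks are
the percentiles {p1, p10, p25, p50, p75, p90, p99}; each training volume's
(p1, p99) pair is mapped affinely onto [0, 4095] and the across-volume mean
of the mapped landmarks defines the standard scale; a new volume is mapped
so its landmarks hit the standard positions exactly, with terminal linear
segments extended beyond p1/p99. The histogram mode is computable
(`preprocess.foreground_mode`) but is not a default landmark: its rank
order relative to fixed percentiles varies across subjects, which would
break the monotone landmark correspondence the piecewise-linear map
requires.

## Correspondence: from mask to a fixed vertex set

All model building happens on a 0.5 mm isotropic grid (cubic interpolation
for intensities, nearest neighbour for masks). Corresponded vertices are
extracted per mask by a deterministic recipe:

1. **Surface extraction.** Surface points are taken from marching cubes on
   the mask smoothed with a 2.5 mm Gaussian. The smoothing scale is set by
   the acquisition: with 3 mm slices, nearest-neighbour upsampling leaves a
   z staircase whose jitter would otherwise dominate the small eigenvalues
   of the shape PCA. Raw voxel centres are the fallback for tiny masks.
2. **Ellipsoid fit and key points.** An axis-aligned algebraic least-squares
   ellipsoid (`A x² + B y² + C z² + D x + E y + F z = 1`) gives the centre
   and radii. The in-plane focal distance `c_xy = √(r_max² − r_min²)` and
   `c_xz = r_min` place four interior reference points
   `F_xy± = (xc, yc ± c_xy/2, zc)` and `F_xz± = (xc ± c_xz/2, yc, zc)`.
   The focal-distance reading is the dimensionally consistent one (mm, not
   mm²); both constants are configurable.
3. **Alpha-shape triangulation** (α = 50 mm) of up to 3000 evenly
   subsampled surface points, built from the Delaunay tetrahedralization by
   keeping tetrahedra with circumradius < α and taking faces that belong to
   exactly one kept tetrahedron. Removing sliver tetrahedra can open tiny
   interior cavities whose boundaries are separate closed components; these
   are discarded by area (any secondary component above 10% of the main
   component's area is instead reported as a topology error).
4. **Ray casting.** From each of the five key points (centre plus the four
   `F` points), rays are cast at 8 azimuths (45° step) × 7 elevations
   (−45°…+45°, 15° step); per ray the farthest Möller–Trumbore intersection
   with the mesh is kept (largest ray parameter breaks ties). Ordering is
   (source, direction)-lexicographic, so vertex *k* is the same anatomical
   spot on every subject: K = 5·8·7 = 280.

The elevation fan deliberately stops at ±45°. Steeper rays meet the gland
near its apex/base, where the surface runs almost parallel to the thick
slices and vertex positions are dominated by slice quantization rather than
anatomy; including them roughly doubles the non-anatomical residual variance
of the PCA. The apex/base surface is still reconstructed — the alpha shape
closes the poles — but no statistical claims are made about pole vertices.

## Shape model

Shapes are rigidly aligned to the first cohort member: centroids matched,
then rotation corrected with the four-quadrant inverse tangent in two steps
— the closed-form planar Procrustes angle `atan2(Σ p×r, Σ p·r)` applied in
the x–y plane and then the x–z plane. (A leading-principal-axis estimate of
the same two angles was evaluated and rejected: on ray-fan vertex clouds the
covariance is dominated by the sampling pattern, producing spurious
10–40° rotations between congruent shapes.) Scale is deliberately not
normalized: size differences are anatomy, and the appearance search must
operate in physical units.

PCA retains the smallest number of modes reaching 98% of total variance
(economy SVD of the n × 3K matrix, i.e. the dual trick). A shape is then
`x = x̄ + Ws·b`, and plausibility is enforced by clamping each coordinate to
`|b_i| ≤ m·λ_i`. The eigenvalue enters the clamp (and the appearance
objective below) **linearly** by default; the classical ASM uses √λ in both
places, and `eigen_scaling="sqrt"` switches to it. The linear form is kept
as the default deliberately — it is the form the method states — and at the
default `m = 2` the clamp is loose (λ has units mm², so `m·λ ≫ √λ`); the
practical regularization comes from discarding the residual orthogonal to
the retained modes, which the projection does in either scaling.

## Appearance model and search

At every vertex an intensity profile of length `2·ns+1` (ns = 2, step one
working voxel = 0.5 mm) is sampled along the outward surface normal with
cubic interpolation; out-of-extent samples take the edge value. Normals come
from a local plane fit (PCA over the 20 nearest vertices of the dense
extraction mesh, smallest principal axis, oriented outward against the
shape centroid); face-normal averaging was evaluated and is noisier on
rasterized surfaces, surviving only as the fallback inside the refinement
loop, where no dense mesh exists.

Profiles from the whole cohort are z-normalized per profile and filtered
with DBSCAN (Euclidean metric, `min_pts = 8`, `eps` from the k-distance
elbow unless given); the largest cluster survives, noise points and minor
clusters are discarded. Per-vertex PCA statistics (mean profile `ḡ`,
eigenvectors `Wg`, eigenvalues `λg`) are kept where a vertex has at least 3
inlier profiles, with a pooled model over all vertices as fallback.
Appearance modes carrying less than 10⁻⁴ of the leading eigenvalue are
dropped: the objective divides by eigenvalues, and numerically negligible
modes would otherwise dominate the cost.

The boundary search evaluates, at candidate offsets `ind = 1 … 2·ns_s+1`
along the normal (search half-length `ns_s`), the Mahalanobis-type cost
`f = Σ_i (bc_i/λg_i)²` with `bc = Wgᵀ(g − ḡ)`, and moves the vertex by
`movement = (ind_min − 1) − ns_s` samples. Ties prefer the smallest
|movement| (damped evolution). Each iteration then aligns the moved shape
to the model frame, clamps `b`, reconstructs, and restores the pose with
the exact inverse alignment.

Four named configurations ship as presets (ASM-1: it 1/ns 8/m 3,
ASM-2: 2/8/1, ASM-3: 2/8/2, ASM-4: 2/8/3); the package default is
(it 2, ns 8, m 2). The preset table and the stated best configuration
disagree in the source material on whether the best m is 1 or 2; both are
preserved rather than silently reconciled.

## Initializer

The initial segmentation is pluggable. The reference architecture
("VNet-T2") is specified as layer metadata: per encoder level two 3×3×3
convolutions (filters `8·2^l` then `8·2^(l+1)`) each followed by instance
normalization, 2×2×2 max pooling ((2,2,1) where z is odd); the decoder uses
transposed convolutions keeping their input channel count, concatenation
skips, and two convolutions per level; the binary head is a single-logit
1×1×1 sigmoid convolution. Instance normalization carries no trainable
parameters. With depth 4, base filters 8 and a 512×512×24×1 input this
totals exactly 1,192,593 trainable parameters, which is the architecture's
acceptance check; the count is computed from the layer list without
allocating weights, and no deep-learning framework is required or used.
Training infrastructure is out of scope; tests and demos use a surrogate
initializer that corrupts the reference mask the way a rough volumetric
prediction is corrupted (below).

## Post-processing

Refined vertices become a mask by: alpha-shape triangulation at α = 30 mm;
per-slice boundary polygons from 32 in-plane rays (11.25° step — finer than
the correspondence step to bound polygon discretization error) cast from
the mesh centroid, keeping the farthest intersection per ray; even-odd
polygon fill per slice; 2D-per-slice then 3D hole filling; 3D morphological
closing with a spherical element of radius 4 working voxels (2 mm); nearest
neighbour downsampling to the native grid. Initial masks additionally pass
through `clean_mask` (largest 26-connected component + hole fill) before
vertex extraction, because a detached false-positive blob can capture
farthest-intersection rays — a documented failure mode of the ray
correspondence.

## Synthetic phantoms: what they emulate and what they do not

The generator mirrors the modeled acquisition at desk scale: a 96×96×24
grid at (1, 1, 3) mm reproduces the 3 mm slice thickness and the
in-plane/through-plane anisotropy with a tractable voxel count, and base
radii (28, 24, 20) mm give a gland of realistic extent. The gland is an
ellipsoid radially modulated by real degree-2 spherical harmonics; cohorts
draw weights `Normal(0, σ_k)` for the symmetric modes Y₂₀ then Y₂₂
(defaults σ = 0.12, 0.05), clipped at 2.5σ. The symmetric modes and the
clip keep the cohort inside the regime where vertex positions respond
linearly to the weights, which is the regime in which a 98%-variance PCA
can recover exactly the generating modes; antisymmetric modes tilt the
shape and alias into the alignment. Images have Gaussian
interior/exterior intensities (140 ± 8 vs 70 ± 8), a random quadratic
multiplicative bias field in [0.9, 1.1], and additive noise (σ = 5).

`corrupt_mask` emulates a rough volumetric network prediction: spatially
correlated boundary displacement (Gaussian field, 8 mm correlation length,
amplitude 12 mm × severity), punched interior holes, and up to two spurious
exterior blobs; severity 0.3 lands the initial DSC in roughly 0.75–0.95
against the reference, the band a usable initializer occupies.

Passing tests on these phantoms demonstrate that the geometry, statistics
and search machinery are correct and that refinement improves a corrupted
initialization whose errors are local and boundary-shaped. They do not
demonstrate performance on patient data: real T2w prostate MR has
structured neighbouring anatomy (bladder, rectum, seminal vesicles) with
similar intensities, Rician rather than Gaussian noise, coil profiles, and
genuinely ambiguous apex/base boundaries, none of which the generator
models.

## Numerical choices and degenerate inputs

* Möller–Trumbore uses a 10⁻¹² determinant cutoff and 10⁻⁹ edge tolerance;
  front- and back-face hits count, negative-t hits do not.
* The per-iteration mesh inside `refine` may exclude a vertex that drifted
  inside the cloud; such vertices fall back to the outward radial direction
  from the centroid instead of aborting the iteration.
* Tetrahedron circumradii are computed from the 3×3 linear system of the
  circumcentre; degenerate (near-coplanar) tetrahedra get infinite radius
  and are never retained.
* `dsc` of two empty masks is defined as 1; `hd95` requires both masks
  non-empty; `rvd` requires a non-empty reference. HD95 is the symmetrized
  maximum of the two directed 95th-percentile surface distances (surface =
  6-connectivity erosion difference, distances by Euclidean distance
  transform with physical spacing); directed variants are exposed.
* Resampling preserves physical extent within one voxel; nearest-mode
  resampling can never introduce values outside {0, 1}.
* Model archives store all arrays in a compressed `.npz` plus a JSON
  sidecar with the ray configuration and provenance (input count, config
  hash, timings); rebuilding from identical inputs is bit-identical.

## Problem sizes

The test suite and the acceptance script run the full synthetic study at
the desk scale above: shape-recovery cohorts of n = 30 across 5 seeds,
refinement studies of 10 held-out cases under all four presets with a model
built from 9 training members, 10,000 ray/triangle oracle pairs, and 20
random mask pairs for the metric oracles. These sizes were chosen so the
whole study reruns from scratch in minutes on one CPU while keeping every
statistical check comfortably away from its decision boundary.

## Known limitations

* The correspondence assumes a star-shaped gland with respect to the five
  key points; strongly concave shapes would violate the farthest-
  intersection rule.
* Alignment has no scale or full 3D rotation component (two planar angles
  only); the method targets a fixed acquisition orientation.
* The elevation cap trades apex/base vertex coverage for statistical
  stability; pole geometry is reconstructed by the alpha shape, not driven
  by image evidence.
* Per-vertex appearance statistics from small cohorts are rank-deficient
  (q ≤ 4); the pooled fallback and the eigenvalue floor keep the objective
  usable, but a larger cohort is strictly better.
* The printed linear eigenvalue scaling makes the b-clamp weak at default
  settings; users wanting the classical behaviour should set
  `eigen_scaling="sqrt"`.
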