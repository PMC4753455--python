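# Methods

This document records the models, conventions and numerical choices
behind `hapi3d`, in pipeline order. All defaults named here are package
choices; every parameter can be overridden through the public API.

## Coordinate and transform conventions

- Volumes are indexed `data[x, y, z]`; a coronal section is
  `data[:, :, k]`. Voxel `i` along an axis with size `d` µm is centered
  at world coordinate `(i + 0.5) · d`, so world coordinates are
  continuous and resolution-independent.
- Transforms use the **pull-back** convention: a transform maps
  *reference* world coordinates to *floating* world coordinates.
  Resampling evaluates the floating image at the transformed centers of
  the target grid. Consequently, registering `ref` against a floating
  image constructed as `resample(ref, T.inverse())` should recover `T`.
- Supported families: `Affine2D`, `Rigid3D` (z-y-x Euler angles, degrees),
  `Affine3D`, cubic B-spline `FFD3D`, and `CompositeTransform`
  (applied left to right). All serialize to JSON.
- Interpolation is linear for intensities and **nearest-neighbour for
  labels and binary masks**, so label sets and mask binarity are
  preserved exactly.

## Section-to-blockface registration (2D)

`register_section` aligns each stained section to the corresponding
block-face photograph plane with multi-scale block matching:

- 3-level image pyramid (coarsest first); block size 21 px, search
  radius 10 px at each level (clamped for small levels).
- Blocks are selected by local intensity variance (top quantile inside
  the reference mask); each is matched by exhaustive normalized
  cross-correlation with parabolic sub-pixel refinement.
- An affine is fitted to the displacement set by trimmed least squares
  (iteratively discarding the worst residuals), and the loop composes
  incremental corrections until convergence.
- A never-degrade guard compares the masked correlation coefficient
  before and after; if registration would lower it, the identity is
  returned with `converged=False`. Sections with too little tissue for
  block selection also fall back to the identity rather than aborting.

## Atlas registration (3D)

`register_rigid_3d` maximizes soft-binned mutual information (hard
reference bins, linear "hat" floating bins, natural log) over 6 rigid
parameters with Powell's method, translations parameterized in
minimum-voxel units, rotation center at the volume center. A
best-so-far guard returns the best parameters ever visited.
`register_affine_3d` refines to a full affine by 3D block matching
(7-voxel blocks, 4-voxel search). `register_ffd` then optimizes a
10×10×10 cubic B-spline lattice with L-BFGS-B on the same soft MI with
an analytic gradient, plus a displacement-magnitude penalty
(weight 1e-3) for regularity. `parcellate` applies the composed
transform to the atlas label volume with nearest-neighbour resampling.

## Stained-pixel classification

The classifier is a per-class Gaussian mixture (full covariance,
3 components per class by default, scikit-learn backend) over a 4-D
pixel feature: R, G, B, and the mean luminance of the 5-pixel cross
neighbourhood (center included; edges replicate). Classes are
`stained` (1), `unstained` (2), `background` (3); label 0 marks
unlabeled training pixels. Classification is a Bayes argmax of
class-prior-weighted likelihoods, ties resolved toward the
lowest-numbered class. `fit_model(..., return_loglik=True)` exposes the
per-class EM log-likelihood trace (one EM step per entry, warm start),
which is non-decreasing up to numerical tolerance — the standard EM
guarantee, asserted in the acceptance suite.

F1 is computed from pixel counts: precision `TP/(TP+FP)`, recall
`TP/(TP+FN)`, `F1 = 2PR/(P+R)`.

In the pipeline, sections are classified **in their native geometry**
and only the resulting binary masks are pulled onto the block-face grid
(nearest-neighbour). Classifying after resampling would feed the model
interpolated colors that never existed in the stain palette and blurs
few-pixel objects below the decision boundary; classifying native
pixels avoids fabricating evidence. On the undistorted phantom this
keeps end-to-end region loads within 0.51% relative of truth. On the
*distorted* phantom, loads still underestimate by ~20%: the phantom's
own distortion rendering linearly interpolates 1.6–3.6 px stain blobs
(a realistic partial-volume effect), which is a property of the
synthetic data, not of the classifier — held-out undistorted noisy
sections are classified with F1 = 1.00.

## Quantification over an ontology

`region_load` computes `load = 100 · stained / region` voxel counts
over the valid planes of a labeled volume. `ontology_quantify` rolls a
hierarchical ontology up from the leaves by **summing integer voxel
counts**, so parent volumes equal child sums exactly and the root load
equals the whole-brain load by construction (no floating-point
averaging of child loads: parents are volume-weighted automatically).
Regions touching the volume boundary are flagged `truncated`; labels
absent from the ontology raise a warning. Planes flagged invalid
(missing sections) are excluded from both numerator and denominator.

## Heat maps and correlation

`aggregate` pools a high-resolution binary mask into a low-resolution
occupancy map (default 125 µm isotropic; the target size must be an
integer multiple of the in-plane voxel size and at least the plane
spacing). Each heat-map voxel stores stained/covered over its
footprint, with invalid planes and non-tissue voxels excluded from the
denominator; `coverage` records the covered fraction and `brain_mask`
flags voxels with ≥ 50% coverage. The coverage-weighted global mean
(`global_load_percent`) therefore equals the whole-brain load exactly
before smoothing — a conservation property asserted to 1e-9.

Smoothing is masked-normalized Gaussian (default σ = 1 heat-map voxel;
an FWHM parameterization is also provided): the map and the coverage
weights are smoothed separately and divided, so occupancy does not leak
into non-tissue. Smoothed maps cannot be smoothed again.
`correlate` computes Spearman rank correlation over voxels inside both
brain masks (SciPy), returning ρ, p and the voxel count.

## Sampling simulation

For a given ROI, per-section stained/ROI voxel counts are computed
once; for each spacing `k`, all `k` phase-offset subsets (sections
`o, o+k, o+2k, …` of the sections actually containing the ROI) are
enumerated. Each subset's load **pools voxel counts over its sections**
(it is not a mean of per-section loads), mirroring how a stereologist
would pool sparse sections. The relative error is
`RE = 100 · |L_subset − L_full| / L_full`; `k = 1` reproduces the
reference exactly, so RE ≡ 0. Group comparisons use the two-sided
Mann–Whitney U test (exact for small samples, average ranks for ties);
profile variability uses the coefficient of variation with the (n−1)
standard deviation.

## The phantom

`make_phantom` renders a fully synthetic study: an ellipsoidal brain
with six anatomical regions (cortex, hippocampus, white matter,
thalamus, cerebellum, brainstem) in a 128×96×60 volume at
25×25×125 µm (defaults), a block-face photograph volume with smooth
texture, and two markers ("abeta" and "cd68" at 0.6× density) laid
down as small disks following per-region rostrocaudal profiles
(uniform, gradient, or a caudal hotspot at 0.78·nz, width 0.06·nz,
6× density). Sections are rendered in a brightfield palette
(stain RGB 110,75,45; tissue 205,160,175; background 246,…), distorted
by per-section affines drawn within declared ranges (≤ 4° rotation,
≤ 5% shear, ≤ 12 px translation by default), and corrupted with
Gaussian noise (σ = 8). Every ground-truth object — label volume, stain
masks, per-section true transforms — is retained, and `write_phantom`
serializes the dataset to a directory the CLI can consume. All
randomness flows from a single integer seed through independent
`numpy` generator streams, making the dataset bit-reproducible.
`training_patches` re-renders undistorted sections with an independent
noise stream, providing labeled patches for training and genuinely
held-out patches for evaluation. Phantom problem sizes (and the smaller
grids used in tests) are package choices made for runtime, not tuned to
any outcome; the generator's defaults were fixed before the validation
experiments and define the study conditions.

## Pipeline and determinism

`run_pipeline` executes mask → reconstruct → segment → parcellate →
quantify → heatmap → correlate → sampling; any failure raises
`PipelineError` tagged with the stage name. The manifest records the
configuration, per-stage reports, and a sha256 digest of every derived
volume's raw bytes, so end-to-end determinism is checkable bit-for-bit:
two runs from identical inputs and seed produce identical manifests.
All stochastic components (GMM initialization, optimizer starts) are
seeded from `PipelineConfig.seed`.
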