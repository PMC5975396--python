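# Methods

This note documents the models implemented in `shapeseg`, the assumptions
they make, the defaults that matter and why, and what the phantom
experiments do and do not demonstrate.

## Data model and conventions

Volumes are regular axis-aligned grids; the world coordinate of voxel index
`(i, j, k)` is `origin + (i, j, k) · spacing` (node-centered, millimetres),
with the x-index fastest as in MetaImage. One convention is used by every
module — registration, profile sampling, voxelization and the evaluation
metrics all agree on it, and a shared test fixture checks it. Masks are
strictly binary and stored as unsigned 8-bit. Non-axis-aligned NIfTI
orientation matrices are rejected rather than silently mishandled; DICOM
and multi-label masks are out of scope.

Voxelization of a closed triangle mesh uses a z-column parity fill: for
every (i, j) column the triangle crossings are accumulated and voxels whose
center lies between an odd and the following even crossing are set. Columns
are jittered by a sub-nanometre epsilon so rays never hit vertices or edges
exactly. Surfaces of masks come from marching cubes at iso-level 0.5 (the
symmetric choice for binary data).

## Free-form deformation registration

The non-rigid transform is the classic cubic B-spline FFD: displacements of
a coarse control lattice (default knot spacing 16 mm, padded one knot beyond
the image so every point has full 4×4×4 support) are interpolated by the
tensor product of the uniform cubic basis. The overall mapping is
`T(x) = S(x) + u(x)` — a 7-parameter similarity pose `S` (rotation,
translation, isotropic scale) plus the additive FFD displacement `u` defined
over the fixed domain.

Two cost functions are provided on the overlap region, sampled trilinearly:
mean squared intensity difference (SSD), and negated mutual information from
a joint histogram (32 bins, intensities clamped to the 1–99 percentile
range, natural-log entropies). MI is *maximized*, i.e. its negation is the
cost. The histogram bin count is capped at `sqrt(n/32)` when the overlap is
small, because a 32×32 joint histogram from a few hundred samples is pure
noise. Out-of-volume samples take a configurable background value.

Optimization is multi-resolution (factors 0.25/0.5/1, never shrinking an
axis below 12 voxels):

* **similarity** — derivative-free Powell search over the 7 parameters, with
  the cost evaluated on a strided subset (≤ 32 768) of fixed-grid voxel
  centers; deterministic, and the per-level trace of accepted costs is
  non-increasing.
* **FFD** — gradient descent with step halving on the control displacements.
  The gradient is analytic: the per-voxel cost derivative with respect to
  the warped moving-image intensity (SSD: residual; MI: difference of joint
  log-likelihood ratios across the linear-interpolation bin pair) is
  multiplied by the moving-image spatial gradient and scattered onto the
  lattice through the separable B-spline weight matrices. A step is accepted
  only if the cost decreases, so accepted traces are monotone per level.
  Default iteration cap 100 per level (40 in the standard experiment, which
  is ample at 64³ — known 4-voxel warps are recovered with ≈ 0.3-voxel mean
  error).

Cost evaluation grids are strided to at most 32 768 points at every level;
the stride preserves grid regularity, so the separable evaluation/scatter
path applies unchanged. These problem sizes keep a full registration at
about six seconds while leaving a large margin on the recovery tolerances.

## Point distribution models

Training shapes (corresponding landmarks, d = 3 by default) are aligned by
generalized Procrustes analysis: each shape is mapped to the current mean by
the least-squares similarity transform (Umeyama, reflections excluded), the
mean is re-estimated and normalized to unit centroid size, until convergence
(1e-8, max 100 iterations). The PCA model uses the 1/N-normalized
covariance of deviations from the mean; when `n·d > N` the N×N Gram matrix
is decomposed instead and mapped back, which is exact. Eigenvector signs
are fixed (largest-magnitude component positive) for reproducibility across
linear-algebra backends. Synthesis optionally clamps each mode weight to
±3√λ — the standard plausibility limit, and the default during ASM search.

Note one deliberate asymmetry: the PDM covariance uses 1/N while the
empirical GP covariance uses 1/(N−1); each module follows the definition
conventional for it, and each is tested against its own formula.

## Gray-level appearance models

Profiles are sampled perpendicular to the boundary at 1-voxel steps of the
current resolution level: 2k+2 trilinear intensity samples symmetric about
the landmark are differenced to a derivative profile of length 2k+1
(centered on the landmark) and normalized by the sum of absolute
differences, zero-safely. "Profile length 8 pixels" is read as k = 4 per
side; a config switch selects the total-length-8 reading instead.

Per landmark and per resolution, the training mean and covariance of these
profiles are stored. The covariance is shrunk toward the scaled identity,
`S + γ (tr S / L) I` with γ = 0.1, before inversion. This matters: with ~10
training cases an L×L (L = 9) sample covariance is rank-deficient, and an
unregularized Mahalanobis distance is dominated by noise eigen-directions —
diagnostics showed fitting quality collapsing without shrinkage while being
flat for γ anywhere in 0.05–1.

The optimal-feature alternative trains one kNN classifier per landmark
(k = 5, brute-force neighbors) on features sampled at ±1..±k voxel offsets
along the normal in every training case, labelled inside (inward) vs
outside (outward). Features per position are the raw intensities of a
3-sample window along the normal plus their two first differences. A
candidate boundary position is scored by the summed absolute disagreement
between the classifier's inside-probabilities along the profile and the
ideal pattern (all inside on one side, all outside on the other); ties —
common, because kNN probabilities are quantized in steps of 1/k — are broken
toward the smallest move.

## Active Shape Model search

Fitting runs at resolutions 0.25/0.5/1 with five iterations each. One
iteration proposes, for every landmark, the best of 6 candidate positions
along the vertex normal of the current mesh (area-weighted normals of the
landmark triangulation), then regularizes the proposal: similarity pose fit
to the proposed points, projection onto the PDM, clamping |b_i| ≤ 3√λ_i,
re-synthesis, and pose re-application. The candidate set always contains
offset 0 (a converged landmark may stay put — without this the truth is not
a fixed point of the iteration) and uses a 0.5-voxel pitch by default: the
source protocol fixes the *number* of candidates, not their spacing, and a
1-voxel pitch measurably stalls convergence at the middle resolution while
half-voxel candidates cost nothing extra.

## Gaussian Process Morphable Models

Deformation fields of a reference surface are modeled as a GP with a
matrix-valued kernel; only kernels of the form `g(x,y)·I₃` ship (Gaussian,
plus sum and scalar-scale combinators), but the decomposition accepts any
PSD kernel. The rank-r Karhunen–Loève basis is computed from the kernel
restricted to the reference vertices: densely when `3V ≤ 1000`, otherwise
via the Nyström method on m seeded uniformly-sampled vertices, implemented
in the numerically symmetric form `B = K_nm C^{-1/2}`, eigendecomposition of
`BᵀB` — the returned basis is exactly orthonormal in both paths and the
dense path is the m = V special case. Kernel-built models retain the
extension data, so basis fields can be evaluated at arbitrary points (used
by the phantom generator to produce exactly corresponding ground truth at
any mesh resolution).

The empirical model from example shapes uses the arithmetic mean field and
the 1/(N−1) sample covariance, factorized through the N×N Gram matrix
(rank ≤ N−1). Correspondence between the reference and a training surface,
when not available by construction, is estimated by GP-regularized surface
registration: alternate closest-point matching with a ridge-regularized
projection of the matched displacements onto the prior basis
(`α = √λ Φᵀr / (λ + η)`), accepting a damped step only when the symmetric
mean closest-point distance decreases. This replaces a coordinate-descent
search considered first: the projection step is exact for an orthonormal
basis, so the alternation is both faster and more accurate, and the
monotone-trace and convergence-flag contracts are unchanged. The prior for
correspondence uses a Gaussian kernel with σ = 0.3× and displacement scale
5 % of the reference bounding-box diagonal, r ≤ 100 — scale-free defaults
recorded in the model archive.

Segmentation of a new image is search by candidate sampling, not
normal-line search: at each of 200 iterations, 20 whole-shape candidates are
drawn around the current best coefficients from the (annealed, σ 1.0 → 0.1)
Gaussian proposal, scored by the summed per-vertex Mahalanobis profile
distance, and the best is kept if it improves. Every accepted state is in
the model span by construction, and a fixed seed makes the run
bit-reproducible. Coefficients are not clamped by default: projections of
held-out shapes onto a 10-sample empirical basis routinely exceed 3
standardized units, so an ASM-style ±3 limit would exclude reachable true
shapes (a clamp remains available). Only prior resampling is implemented —
the model is not conditioned on accepted candidates during fitting.

Pose: the phantom cohorts are generated in one common frame, mirroring a
pipeline whose first stage rigidly registers all inputs; the estimators
therefore default to no extra pose initialization (`GPMMSegmenter
init='none'`, ASM `init='mean'`). An Otsu-moments initializer (centroid +
bounding-volume scale) is available for unaligned data; note that ASM
refits pose at every iteration and tolerates an imperfect initial pose,
while the GPMM search cannot correct a pose error outside its span.

## Evaluation metrics

DICE is reported in percent; two empty masks score 100 by the 0/0
convention (logged). Mean surface distance is the *symmetric mean*
`(Σ d_i + Σ d_j)/(n_X + n_Y)` of closest distances between the two surface
point sets — the product form sometimes printed for this quantity is
dimensionally inconsistent with a mean distance in mm and is treated as a
typo. Hausdorff is the maximum of the two directed sup-inf distances. Mask
surfaces are the boundary voxels (foreground with a background 6-neighbor)
at voxel centers; closest-point queries use a KD-tree and are tested to
agree exactly with O(n²) brute force.

## Phantom generator

Each cohort draws per-case coefficients from a standard normal (per-case
seeded substreams of one master seed), deforms a deterministic reference
organ — a 70 mm lobed ellipsoid, asymmetric so rigid self-alignment is
impossible — by the known low-rank GP, voxelizes the mesh, and renders
interior 100 / exterior 0 intensities smoothed by a 1-voxel Gaussian with
additive N(0, 15) noise on a 64³ grid at 2 mm. The deformation GP uses a
Gaussian kernel with σ = 0.3 × organ diameter, rank 5, scaled so the
expected RMS vertex displacement is 6 % of the diameter. Self-intersecting
draws are rejected and regenerated from the next substream. The defaults
are chosen as CT-like desk-scale conditions (liver ≈ 100 HU over soft-tissue
background, realistic contrast-to-noise) and are fixed: experiments, tests
and the acceptance script all run these same conditions.

What the phantoms emulate: organ-scale smooth shape variation, two-tissue
contrast, partial-volume blur, acquisition noise, exact correspondences.
What they do not: neighboring organs and clutter, intensity
inhomogeneity, pathology, pose/scale variation between subjects, rater
disagreement in the reference masks, and anisotropic slice spacing (the I/O
and registration support it; the default cohort does not exercise it).
Passing the phantom experiments therefore demonstrates correctness of the
machinery and the expected *relative* ordering of the methods under known
conditions — not clinical-grade performance on real CT.

## Standard experiment

The default comparison generates 20 phantoms, splits 10/10, trains every
method on the training split and evaluates on the held-out cases: atlas
propagation with SSD and with MI (plus both re-run on test images passed
through a strong monotone logistic intensity remap, which preserves MI's
ranking but breaks SSD's assumption of comparable intensity scales), both
ASM variants, and the GPMM at 500/1000/2000 model vertices. ASM and GPMM
train on the generator's exact correspondences (the generator makes them
available by construction; GP-estimated correspondence is config-selectable
and exercised by its own tests). Expected behavior at these conditions:
GPMM above both ASM variants, ASM above single-atlas, MI ≥ SSD under the
remap, GPMM non-decreasing with vertex count, all reproduced from one seed
in roughly ten minutes on one CPU.

## Numerical choices and degenerate inputs

* Registration refuses constant images and transforms leaving < 10 %
  overlap; a constant overlap makes MI 0 with a warning.
* Masks touching the grid border cannot form a closed isosurface; callers
  choose between an error (default) and zero-padding.
* Procrustes rejects all-coincident shapes; a single training shape yields a
  zero covariance with a warning; empirical GPs require N ≥ 2 (the 1/(N−1)
  normalization is undefined otherwise).
* Requested GP ranks beyond the positive spectrum are truncated with a
  warning; eigenvalues below 1e-12 of the leading one are treated as zero.
* All RNG flows through `numpy.random.Generator` objects derived from
  explicit seeds; no global state is used.
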