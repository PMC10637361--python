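# Methods

This note documents the models, conventions and numerical choices behind
tfusplan, and what the synthetic phantoms do and do not demonstrate.

## Coordinate conventions

World coordinates are RAS-like with **+x toward the patient's left**,
+y anterior, +z superior, so the "14 mm lateral" offset of the standard
target is +14 for a left-side treatment and −14 for a right-side one.
Voxel indices are 0-based and voxel *centers* map through the 4×4 affine
(NIfTI convention); 4D volumes keep the gradient axis last. The AC-PC
transform places the PC at the origin with the PC→AC direction along +y;
its rotation is the minimal rotation taking that direction onto +y, so no
roll about the AC-PC axis is introduced. An optional roll correction is
estimated by rigidly registering the reoriented image to a user-supplied
AC-PC-aligned reference and keeping only the rotation component about +y.

## Standard target coordinate

`target = PC + 0.25·d·(PC→AC) + (±14, 0, 1) mm` with `d` the straight-line
AC-PC distance. The 25% rule uses the chord, not an arc length; "superior"
is +z of the convention above. Landmark pairs closer than 5 mm are rejected
as degenerate (a physiological AC-PC distance is 20–30 mm). The constants
14 mm (lateral) and 1 mm (superior) are exposed as named module constants
bound to the rule, not free parameters: the lateral deviation statistic
`xdev` references the same 14.

## Rigid registration with normalized gradient fields

The NGF distance compares local gradient orientations and is therefore
invariant to monotone affine intensity rescaling, which is what makes
T1→DWI alignment feasible without an intensity model. The edge parameter ε
decides which gradients count as structure; the default is 1% of the 99th
percentile of the fixed image's gradient magnitude. Two properties of the
practical objective are worth knowing:

- With ε > 0 the optimum for two identical images is displaced from the
  identity by O(ε²) (about 0.008 mm at the default ε on the blob phantom
  used in the tests). Registration of *clean, identical* images should use
  a smaller ε; for noisy data the default is the robust choice.
- Averaging over the (changing) overlap region slightly rewards transforms
  that push low-gradient voxels out of the moving grid, displacing optima
  by a few tenths of a millimetre on phantoms with empty background. The
  optional `interior_margin_mm` config restricts the evaluated sample to an
  interior region of the fixed grid; when the margin exceeds the expected
  misalignment the sample set never leaves the moving image, the overlap is
  constant, and the bias vanishes. The recovery experiments use an 11 mm
  margin for perturbations up to 5 mm / 10°.

The solver is L-BFGS-B over (translation mm, Euler angles deg) about the
fixed-image center, on a 3-level pyramid (downsample ×2 with a 1-voxel
Gaussian antialias per level). Robustness additions, all deterministic: the
coarsest level tries ±6° single-axis rotation starts besides the warm
start and keeps the best; an aborted line search (the objective is only
piecewise smooth under trilinear interpolation) triggers up to two L-BFGS
restarts from the current point; the finest level solves on a stride-2
subsample of the fixed grid and then polishes at full sampling with
central-difference gradients, which do not stall at the grid-aligned kinks
where forward differences do. Translation is initialized from the offset of
the two fields of view so grids with different world origins start within
capture range.

## DTI preprocessing

Pipeline order: Lanczos-3 supersampling → Gaussian smoothing → tensor fit
(order configurable). Supersampling to 1 mm isotropic adds no information
but lets the tracker use cheap trilinear interpolation at sub-voxel steps.
The Lanczos weights of each output sample are renormalized to sum to 1, so
constant signals are reproduced exactly (DC-exact); output grids preserve
the world extent of the input. Gaussian smoothing takes σ in world mm
(default 1.0 mm) and is applied per frame.

The tensor fit solves `log(S_k/S0) = −b_k gₖᵀ D gₖ` by unweighted linear
least squares over the weighted frames, with S0 the mean of the b=0 frames.
Voxels with non-positive S0 or any non-positive weighted signal are masked
out with a zero tensor. Negative eigenvalues are clamped to zero for
derived quantities (FA, color maps, tracking) but the raw tensor is kept.
At least 6 weighted directions spanning all six tensor degrees of freedom
are required (checked via the design-matrix rank).

Noise sensitivity of the unweighted log-linear estimator: with noise of
constant per-measurement relative magnitude (σ_k ∝ S_k) at SNR 20, the
median relative eigenvalue error over random SPD tensors is ≈2.5%. With
additive noise referenced to the b0 signal (σ = S0/SNR, the phantom's
convention), strongly attenuated frames carry much lower per-sample SNR and
the median error grows to ≈5–8%; degenerate prolate tensors are worst
because eigenvalue sorting repels the nearly equal minor eigenvalues. A
weighted or iterative fit would reduce this but is deliberately out of
scope: the plain log-linear solution is the direct solution of the signal
model.

## Bundles, ROI roles and adaptive parameters

Each bundle is a seed ROI, an unordered set of include ROIs (every
accepted streamline must visit all of them), and exclude ROIs (touching
any rejects the streamline). The default definitions, with laterality
resolved against the treated (ipsilateral) side:

| bundle | seed | include | exclude | cap |
|---|---|---|---|---|
| CTT | precentral gyrus | contralateral dentate nucleus, contralateral superior cerebellar peduncle, ipsilateral red nucleus, ipsilateral thalamus | — | 2500 |
| PTT | globus pallidus interna | frontal thalamus | — | 500 |
| CST | precentral gyrus | ipsilateral cerebral peduncle, ipsilateral posterior limb of the internal capsule | ipsilateral thalamus | 500 |
| ML | midbrain portion of the ML | ipsilateral postcentral gyrus, ipsilateral thalamus | — | 500 |

The CTT's cerebellar members are contralateral because the tract
decussates in the superior cerebellar peduncle. All bundles require 100
accepted fibers. The CTT's extended iteration cap reflects how rarely a
cortical-seeded streamline threads both the small red nucleus and the
thalamus.

Tracking parameters (step 1 mm, FA stop 0.15, bend limit 45°, length
20–200 mm by default) are resolved per position by a nearest-voxel lookup
in an integer label atlas; labels are never interpolated, so the parameter
field is piecewise constant on the atlas grid. Published per-region values
for a specific white-matter atlas are not part of this package; the map
ships with one default set and a YAML override schema keyed by label id.

## Streamline integration

Fixed-step Euler on the principal eigenvector of the trilinearly
interpolated tensor (interpolate the 6 components, then eigendecompose),
bidirectional from the seed with the two half-tracks concatenated
seed-centered. The eigenvector sign is chosen for continuity (non-negative
dot product with the previous direction). Termination per direction: FA
below the local threshold, bend angle above the local limit, leaving the
grid, or exceeding the local maximum length; tracks shorter than the local
minimum length are rejected. Because directions are unit vectors, every
consecutive point pair is exactly one local step apart — an invariant the
tests check to 1e-6 mm. A second-order (midpoint) integrator was
considered and rejected: at half-voxel steps on supersampled data the
Euler error is already well below the voxel scale, and fixed steps keep
the step-length invariant exact.

The bundle loop seeds `batch_size` (default 100) points per iteration:
uniformly chosen seed-ROI voxels with uniform jitter inside each voxel,
all drawn from one `numpy` PCG64 generator seeded by the caller, which
makes bundles bit-for-bit reproducible. ROI membership is nearest-voxel
containment of any streamline point, without dilation.

## Probability maps and thresholds

Each accepted streamline contributes at most once per voxel; counts are
divided by the number of accepted streamlines and rescaled so the maximum
is 1. (Per-seed-voxel normalization would differ only by this final
rescale.) Thresholds are inclusive: adaptive-tracker maps keep voxels
≥ 0.2 (CTT/PTT/CST) or ≥ 0.5 (ML); maps from a probabilistic FSL-style
pipeline keep ≥ 0.1. The asymmetry exists because probabilistic maps decay
smoothly toward the bundle border while deterministic-streamline maps are
more plateau-like; the chosen values give comparable bundle diameters.

## Evaluation statistics

`dev` and `xdev` are per-patient means over therapeutic sonication points
(temperature ≥ 55 °C, inclusive); cohort means average the per-patient
statistic over the patients satisfying a caller-supplied condition.
`xdev` uses the magnitude of the lateral component, `| |p_x| − 14 |`, so
one formula serves both treated sides; a signed variant would be
meaningful only for a single-side cohort. Point-to-bundle distance is 0
inside a suprathreshold voxel and otherwise the minimum distance to
suprathreshold voxel centers — a border distance, not a centerline
distance. Dice of two empty masks is an error, not 0.

## Synthetic phantoms

`make_phantom` builds a 64³ grid at 1 mm (defaults) containing a straight
corridor or a quarter-circle arc (radius 20 mm) of prolate tensors with
eigenvalues (1.7, 0.3, 0.3)×10⁻³ mm²/s — FA ≈ 0.80, typical of coherent
white matter — in an isotropic background of 0.7×10⁻³ mm²/s. DWI signals
are forward-simulated on a 57-frame single-shell scheme (one b=0, 56
spherical-Fibonacci directions at b = 1200 s/mm²) with additive Gaussian
noise at SNR 20 on the b0 signal by default (Rician optional; `none` for
oracle tests). Spheres of 3-voxel radius on the centerline serve as seed,
waypoint and target ROIs, one off-corridor sphere as an exclude/unreachable
include; a 1-voxel-radius "hard mode" exercises small-waypoint behaviour.
A two-label atlas splits the corridor at its midpoint so region-adaptive
parameters are actually exercised (the written dataset overrides the step
size in the distal half). AC/PC landmarks are placed 24 mm apart, already
AC-PC aligned; a spherical lesion sits at the corridor midpoint; the
treatment log samples five points around the standard coordinate
(σ = 1 mm) with temperatures straddling 55 °C.

What the phantom does **not** emulate: curved anatomy beyond a single arc,
crossing or kissing fibers, susceptibility or eddy distortions, partial
volume with CSF, Rician noise floors at low SNR, or realistic T1 contrast.
Passing tests therefore demonstrate the geometric and algorithmic
contracts of the pipeline — not clinical accuracy on patient data, which
additionally depends on segmentation quality the pipeline takes as input.

## Numerical choices and experiment sizes

- Arc-length check: the tracked length of the arc phantom is compared to
  the analytic `R·π/2` with step 0.5 mm (the half-voxel rule at 1 mm
  resolution) and FA stop 0.5 — the FA of the 50/50 bundle/background
  tensor blend at the tube boundary, which makes termination unbiased at
  the flat end caps. With the generic 0.15 stop the track overshoots the
  caps by up to a voxel per end, measuring corridor-plus-fringe rather
  than arc length.
- Registration recovery experiments: 20 random transforms (≤5 mm, ≤10°)
  on 40³ sum-of-signed-Gaussian phantoms whose blob centers are mapped
  analytically through the true transform, so the moving image carries no
  resampling error and the exact optimum is known. Worst-case recovery in
  this suite is ≈0.04 mm / 0.1°.
- The unreachable-include iteration-cap experiment uses a batch size of 1;
  the cap semantics are batch-size-independent and the small batch keeps
  the 2,500-iteration run to ~20 s.
- Plan runs are deterministic: NIfTI outputs are written uncompressed with
  fixed headers, JSON with sorted keys, and per-stage wall times go only
  to `plan.log`, the single file excluded from byte-identity.
- Eigen-decompositions use `numpy.linalg.eigh` with eigenvalues reordered
  descending; FA is computed from eigenvalues clamped at zero and is set
  to 0 where the tensor norm vanishes.

## Known limitations

Deformable atlas registration is out of scope — the label atlas must
already be in DWI space. ROI segmentation is out of scope — masks are
inputs, and the Dice utilities exist to *evaluate* externally produced
segmentations. Single-tensor fitting cannot represent crossing fibers;
the tracker follows the principal eigenvector only. The treatment-log
dialect is a documented CSV (patient, x, y, z, temp_c in AC-PC mm),
standing in for vendor-specific formats.
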