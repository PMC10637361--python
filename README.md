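# tfusplan

Automatic treatment planning for transcranial MR-guided focused ultrasound
(tcMRgFUS) ablation in essential tremor: the geometric stereotactic target,
diffusion-tensor preprocessing, atlas-adaptive ROI-constrained streamline
tractography of the clinically relevant bundles, and the distance statistics
used to evaluate a plan. The package is aimed at neuroimaging-methods
researchers and engineers who need a tested, scriptable reference
implementation of this pipeline; every stage is driven end-to-end by fully
synthetic tensor phantoms, so nothing has to be downloaded to run, test or
extend it.

## What it computes

**Standard target coordinate.** After reorienting the head so the anterior
and posterior commissures (AC, PC) share an axial plane with the AC-PC line
along +y, the ablation target near the ventral intermediate nucleus (VIM) is

```
target = PC + 0.25 · |AC − PC| · ŷ + 1 mm · ẑ ± 14 mm · x̂
```

with the lateral sign set by the treated side (+x is the patient's left).

**DTI preprocessing.** The DWI volume is supersampled to an isotropic grid
with a separable Lanczos-3 kernel (`L(x) = sinc(x)·sinc(x/3)` for `|x| < 3`),
smoothed with a Gaussian in world millimetres, and fitted per voxel with the
log-linear least-squares solution of the Stejskal–Tanner model
`S_k = S0 · exp(−b_k gₖᵀ D gₖ)`.

**Rigid registration.** T1-to-DWI alignment minimizes the
normalized-gradient-fields (NGF) distance

```
D(t) = mean_x [ 1 − ⟨∇f(x), ∇m(t(x))⟩² / ((‖∇f‖²+ε²)(‖∇m‖²+ε²)) ]
```

over 6 rigid parameters with L-BFGS on a coarse-to-fine pyramid; NGF compares
edge orientations, so it is insensitive to the intensity differences between
anatomical and diffusion images.

**Tractography.** Deterministic principal-eigenvector streamlines (fixed-step
Euler, trilinear tensor interpolation, bidirectional from each seed) with
per-position parameters (step, FA stop, bending limit, length bounds) looked
up in an integer atlas, so tracking adapts locally to white-matter regions.
Four bundles are predefined with seed / include / exclude ROI roles: the
cerebellothalamic (CTT) and pallidothalamic (PTT) target tracts and the
corticospinal tract (CST) / medial lemniscus (ML) no-go tracts. A bundle is
re-seeded until at least 100 streamlines satisfy all ROI constraints, capped
at 500 iterations (2,500 for the CTT, whose small red-nucleus waypoint makes
acceptance rare). Accepted streamlines become visitation probability maps
scaled to [0, 1] and thresholded at 0.2 (0.5 for the ML; 0.1 for maps from a
probabilistic FSL-style pipeline, all inclusive).

**Evaluation.** Sonication points reaching a maximum average temperature of
at least 55 °C count as therapeutic. For patient *j* with points `p(i,j)`,

```
dev(j)  = (1/K) Σᵢ ‖p(i,j) − target(j)‖
xdev(j) = (1/K) Σᵢ | |pₓ(i,j)| − 14 |
```

plus conditional cohort means of either statistic, point-to-bundle border
distances on thresholded maps, lesion centroids, and Dice overlap.

## Worked example

```
$ python examples/standard_target.py
AC-PC distance: 26.0 mm
 left: (+14.0, +6.5, +1.0) mm
right: (-14.0, +6.5, +1.0) mm
```

The anterior offset is 25% of the 26 mm AC-PC distance; the sides mirror in x.

```
$ python examples/track_bundle_phantom.py
accepted fibers:   100 (of 100 candidates, 1 iteration(s))
fiber length:      50.0 - 51.0 mm (corridor is 48 mm)
probability map:   1316 visited voxels, 1089 survive the 0.2 threshold
```

On a clear straight corridor every candidate streamline satisfies the
seed→include constraint, so the minimum fiber count is reached in one
iteration; tracked lengths slightly exceed the nominal corridor because
termination happens where the interpolated FA crosses the stop threshold,
about half a voxel outside the tube.

The whole pipeline — reorientation, standard coordinate, tensor fit, four
bundles, thresholded maps, evaluation — runs on a generated dataset with
`python examples/end_to_end_plan.py`, or from the shell:

```
tfusplan make-phantom --out ds --seed 42
tfusplan plan --config ds/plan.yaml --out out --seed 42
```

Repeated runs with the same config are byte-identical (timings go to
`plan.log` only).

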