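"""Atlas-adaptive deterministic streamline tractography.

Streamlines follow the principal eigenvector of the trilinearly
interpolated diffusion tensor with fixed-step Euler integration,
bidirectionally from each seed.  At every position the step size, FA stop
threshold, bending limit and length bounds come from the region parameter
map via a nearest-voxel atlas lookup, so tracking behaviour adapts to the
white-matter region being traversed.  A bundle is tracked by repeatedly
seeding batches inside the seed ROI until at least ``min_fibers``
streamlines have traversed every include ROI while avoiding all exclude
ROIs, or until the iteration cap is reached.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional
import warnings

import numpy as np

from .errors import (
    EmptyBundleError,
    EmptyMaskError,
    OutOfBoundsError,
    ValidationError,
)
from .dti import TensorField, components_to_matrices, fa_from_eigenvalues
from .rois import BundleSpec, RegionParameterMap, ROISet, TrackingParameters
from .volumes import Volume

__all__ = [
    "Streamline",
    "StreamlineBundle",
    "ProbabilityMap",
    "track_streamline",
    "track_bundle",
    "probability_map",
    "threshold_map",
    "default_threshold",
    "save_bundle_trk",
    "save_bundle_summary",
]

#: Probability-map thresholds: the adaptive tracker's maps are cut at 0.2
#: (0.5 for the ML); maps from a probabilistic FSL-style pipeline at 0.1.
#: All thresholds are inclusive (values >= threshold are retained).
AFT_THRESHOLDS = {"CTT": 0.2, "PTT": 0.2, "CST": 0.2, "ML": 0.5}
FSL_THRESHOLD = 0.1

#: Seeds drawn per retry-loop iteration (not specified by the iteration
#: contract; configurable).
DEFAULT_BATCH_SIZE = 100


@dataclass
class Streamline:
    """An ordered world-mm polyline with an accept/reject status."""

    points: np.ndarray  # (n, 3)
    status: str         # "accepted" | "rejected"
    reason: Optional[str] = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    @property
    def length_mm(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class StreamlineBundle:
    name: str
    streamlines: List[Streamline]
    iterations_used: int
    rng_seed: int
    n_candidates: int = 0

    @property
    def n_accepted(self) -> int:
        return len(self.streamlines)


@dataclass
class ProbabilityMap:
    """Visitation frequencies scaled to [0, 1] on a template grid."""

    volume: Volume
    threshold: Optional[float] = None


class _TensorSampler:
    """Trilinear interpolation of the 6 tensor components plus fast
    eigen-analysis, with precomputed world<->voxel maps."""

    def __init__(self, tf: TensorField):
        self.tensors = tf.tensors
        self.shape = np.array(tf.spatial_shape)
        A = np.asarray(tf.affine, dtype=float)
        self.Ainv3 = np.linalg.inv(A)[:3, :3]
        self.Ainvt = np.linalg.inv(A)[:3, 3]

    def world_to_voxel(self, p: np.ndarray) -> np.ndarray:
        return self.Ainv3 @ p + self.Ainvt

    def sample(self, p: np.ndarray):
        """FA and principal eigenvector at world point p, or None if the
        point leaves the grid."""
        v = self.world_to_voxel(p)
        if np.any(v < 0) or np.any(v > self.shape - 1):
            return None
        i0 = np.floor(v).astype(int)
        i0 = np.minimum(i0, self.shape - 2)
        f = v - i0
        block = self.tensors[i0[0]:i0[0] + 2, i0[1]:i0[1] + 2, i0[2]:i0[2] + 2]
        wx = np.array([1 - f[0], f[0]])
        wy = np.array([1 - f[1], f[1]])
        wz = np.array([1 - f[2], f[2]])
        w = wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
        c6 = np.tensordot(w, block, axes=([0, 1, 2], [0, 1, 2]))
        D = components_to_matrices(c6)
        evals, evecs = np.linalg.eigh(D)
        evals = np.clip(evals[::-1], 0.0, None)
        e1 = evecs[:, ::-1][:, 0]
        fa = float(fa_from_eigenvalues(evals))
        return fa, e1


def _track_half(
    sampler: _TensorSampler,
    seed: np.ndarray,
    direction: np.ndarray,
    atlas: Volume,
    pm: RegionParameterMap,
    params_lookup,
) -> List[np.ndarray]:
    """Integrate one direction from the seed; returns points after the seed."""
    pts: List[np.ndarray] = []
    p = seed.copy()
    prev_dir = direction / np.linalg.norm(direction)
    length = 0.0
    first = True
    while True:
        params = params_lookup(p)
        res = sampler.sample(p)
        if res is None:
            break  # leaving the grid
        fa, e1 = res
        if fa < params.fa_threshold:
            break
        d = e1 if float(np.dot(e1, prev_dir)) >= 0 else -e1
        if not first:
            cosang = float(np.clip(np.dot(d, prev_dir), -1.0, 1.0))
            if np.degrees(np.arccos(cosang)) > params.max_angle_deg:
                break
        if length + params.step_mm > params.max_length_mm:
            break
        p = p + params.step_mm * d
        length += params.step_mm
        pts.append(p.copy())
        prev_dir = d
        first = False
    return pts


def track_streamline(
    tf: TensorField,
    seed,
    atlas: Volume,
    pm: RegionParameterMap,
    rng=None,
) -> Streamline:
    """Bidirectional principal-eigenvector streamline from a world-mm seed.

    Termination per direction: FA below the local threshold, bending angle
    above the local limit, leaving the grid, or exceeding the local
    maximum length.  Tracks shorter than the local minimum length are
    rejected; the two half-tracks are concatenated seed-centered.  The
    ``rng`` argument is accepted for interface symmetry but unused: the
    integration is deterministic.
    """
    from .rois import params_at  # local import to keep module deps one-way

    seed = np.asarray(seed, dtype=float).reshape(3)
    sampler = _TensorSampler(tf)
    if sampler.sample(seed) is None:
        raise OutOfBoundsError(f"seed {seed} outside the tensor grid")

    cache: dict = {}

    def params_lookup(p: np.ndarray) -> TrackingParameters:
        key = tuple(np.rint(atlas.world_to_voxel(p)).astype(int))
        if key not in cache:
            cache[key] = params_at(pm, atlas, p)
        return cache[key]

    seed_params = params_lookup(seed)
    fa, e1 = sampler.sample(seed)
    if fa < seed_params.fa_threshold:
        return Streamline(np.array([seed]), "rejected", "low-FA")

    fwd = _track_half(sampler, seed, e1, atlas, pm, params_lookup)
    bwd = _track_half(sampler, seed, -e1, atlas, pm, params_lookup)
    points = np.array(list(reversed(bwd)) + [seed] + fwd)
    sl = Streamline(points, "accepted")
    if sl.length_mm < seed_params.min_length_mm:
        return Streamline(points, "rejected", "too-short")
    return sl


def _mask_lookup(mask: Volume):
    shape = np.array(mask.spatial_shape)
    data = np.asarray(mask.data, dtype=bool)
    inv = np.linalg.inv(mask.affine)

    def hits(points: np.ndarray) -> bool:
        vox = np.rint(points @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        if not np.any(ok):
            return False
        return bool(np.any(data[tuple(vox[ok].T)]))

    return hits


def track_bundle(
    spec: BundleSpec,
    rs: ROISet,
    tf: TensorField,
    atlas: Volume,
    pm: RegionParameterMap,
    rng_seed: int,
    batch_size: int = DEFAULT_BATCH_SIZE,
) -> StreamlineBundle:
    """Track one bundle with the min-fiber / max-iteration retry loop.

    Each iteration samples ``batch_size`` seed points uniformly over the
    seed-ROI voxels (uniform jitter inside each chosen voxel), tracks
    them, and keeps streamlines that traverse every include ROI and touch
    no exclude ROI.  The loop stops once the accepted count reaches
    ``spec.min_fibers`` or after ``spec.max_iterations`` iterations.
    Bit-exact reproducible for a fixed ``rng_seed``.
    """
    if spec.seed_roi not in rs:
        raise ValidationError(f"seed ROI {spec.seed_roi!r} not in ROI set")
    seed_mask = rs[spec.seed_roi]
    seed_vox = np.argwhere(seed_mask.data)
    if len(seed_vox) == 0:
        raise EmptyMaskError(f"seed ROI {spec.seed_roi!r} is empty")
    include_tests = [_mask_lookup(rs[n]) for n in spec.include_rois]
    exclude_tests = [_mask_lookup(rs[n]) for n in spec.exclude_rois]

    rng = np.random.default_rng(rng_seed)
    accepted: List[Streamline] = []
    iterations = 0
    n_candidates = 0
    while iterations < spec.max_iterations and len(accepted) < spec.min_fibers:
        iterations += 1
        picks = seed_vox[rng.integers(0, len(seed_vox), size=batch_size)]
        jitter = rng.uniform(-0.5, 0.5, size=(batch_size, 3))
        seeds = seed_mask.voxel_to_world(picks + jitter)
        for seed in seeds:
            n_candidates += 1
            try:
                sl = track_streamline(tf, seed, atlas, pm)
            except OutOfBoundsError:
                continue
            if sl.status != "accepted":
                continue
            if any(t(sl.points) for t in exclude_tests):
                continue
            if not all(t(sl.points) for t in include_tests):
                continue
            accepted.append(sl)
    return StreamlineBundle(
        name=spec.name,
        streamlines=accepted,
        iterations_used=iterations,
        rng_seed=int(rng_seed),
        n_candidates=n_candidates,
    )


def probability_map(bundle: StreamlineBundle, grid: Volume) -> ProbabilityMap:
    """Voxelwise visitation probability on the template grid.

    Each accepted streamline contributes at most once per voxel; counts
    are divided by the number of accepted streamlines and rescaled so the
    maximum is 1.
    """
    if bundle.n_accepted == 0:
        raise EmptyBundleError(f"bundle {bundle.name} has no accepted streamlines")
    shape = grid.spatial_shape
    counts = np.zeros(shape, dtype=float)
    inv = np.linalg.inv(grid.affine)
    for sl in bundle.streamlines:
        vox = np.rint(sl.points @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        ok = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
        if not np.any(ok):
            continue
        uniq = np.unique(vox[ok], axis=0)
        counts[tuple(uniq.T)] += 1.0
    counts /= bundle.n_accepted
    peak = counts.max()
    if peak > 0:
        counts /= peak
    return ProbabilityMap(Volume(counts, grid.affine.copy()), threshold=None)


def default_threshold(bundle_name: str, pipeline: str = "AFT") -> float:
    if pipeline == "FSL":
        if bundle_name not in AFT_THRESHOLDS:
            raise ValidationError(f"unknown bundle name {bundle_name!r}")
        return FSL_THRESHOLD
    if pipeline != "AFT":
        raise ValidationError(f"unknown pipeline {pipeline!r}")
    try:
        return AFT_THRESHOLDS[bundle_name]
    except KeyError:
        raise ValidationError(f"unknown bundle name {bundle_name!r}") from None


def threshold_map(
    p: ProbabilityMap,
    bundle_name: str,
    pipeline: str = "AFT",
    threshold: Optional[float] = None,
) -> ProbabilityMap:
    """Zero out sub-threshold voxels; retention is inclusive (>=)."""
    if p.threshold is not None:
        raise ValidationError("probability map is already thresholded")
    thr = default_threshold(bundle_name, pipeline) if threshold is None else threshold
    data = np.where(p.volume.data >= thr, p.volume.data, 0.0)
    if not np.any(data):
        warnings.warn(
            f"{bundle_name}: all probability values below threshold {thr}",
            stacklevel=2,
        )
    return ProbabilityMap(Volume(data, p.volume.affine.copy()), threshold=thr)


def save_bundle_trk(bundle: StreamlineBundle, grid: Volume, path) -> None:
    """Export accepted streamlines as TrackVis .trk (world-space points)."""
    import nibabel.streamlines as nbs

    tractogram = nbs.Tractogram(
        [sl.points for sl in bundle.streamlines], affine_to_rasmm=np.eye(4)
    )
    header = {
        "voxel_sizes": tuple(float(s) for s in grid.spacing),
        "dimensions": tuple(int(n) for n in grid.spatial_shape),
        "voxel_to_rasmm": grid.affine.astype(np.float32),
        "voxel_order": "RAS",
    }
    nbs.TrkFile(tractogram, header=header).save(str(path))


def save_bundle_summary(bundle: StreamlineBundle, path) -> None:
    summary = {
        "name": bundle.name,
        "n_accepted": bundle.n_accepted,
        "n_candidates": bundle.n_candidates,
        "iterations_used": bundle.iterations_used,
        "rng_seed": bundle.rng_seed,
        "mean_length_mm": (
            float(np.mean([sl.length_mm for sl in bundle.streamlines]))
            if bundle.n_accepted
            else 0.0
        ),
    }
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
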