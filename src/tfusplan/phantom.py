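"""Synthetic tensor phantoms emulating a complete planning dataset.

A phantom is a 3D grid containing one coherent fiber bundle — a straight
corridor or a circular arc — of prolate tensors whose principal axis
follows the centerline, embedded in an isotropic background.  From the
ground-truth tensor field the generator simulates diffusion-weighted
signals, places seed/include/exclude ROIs on and off the corridor, an
integer atlas that partitions the corridor (so region-adaptive tracking
parameters are exercised), AC/PC landmarks, a spherical lesion near the
corridor midpoint, and a treatment log whose temperatures straddle the
55 deg C therapeutic threshold.  Everything is deterministic under the
spec's seed, so the phantom doubles as the package's reproducible test
fixture and as a runnable end-to-end demo dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .acpc import standard_coordinate
from .errors import ValidationError
from .dti import TensorField, matrices_to_components
from .rois import BundleSpec, ROISet
from .volumes import (
    DiffusionScheme,
    LandmarkPair,
    Volume,
    save_landmarks,
    save_scheme,
    save_volume,
)

__all__ = [
    "PhantomSpec",
    "PhantomData",
    "make_scheme",
    "make_phantom",
    "phantom_bundle_specs",
    "write_phantom_dataset",
    "smooth_blob_volume",
]


@dataclass
class PhantomSpec:
    """Study conditions for a synthetic planning dataset.

    Defaults mirror the clinical acquisition they stand in for: a 64 mm
    cube at 1 mm isotropic resolution, bundle eigenvalues
    (1.7, 0.3, 0.3) x 10^-3 mm^2/s (FA ~ 0.81, typical of coherent white
    matter), an isotropic background at 0.7 x 10^-3 mm^2/s, and Gaussian
    noise at SNR 20 on the b=0 signal.
    """

    shape: tuple = (64, 64, 64)
    spacing_mm: float = 1.0
    geometry: str = "straight"        # "straight" | "arc"
    bundle_radius_mm: float = 4.0
    arc_radius_mm: float = 20.0
    eigenvalues: tuple = (1.7e-3, 0.3e-3, 0.3e-3)
    background_diffusivity: float = 0.7e-3
    s0: float = 1000.0
    noise: str = "gaussian"           # "none" | "gaussian" | "rician"
    snr: float = 20.0
    seed: int = 42
    roi_radius_vox: float = 3.0
    side: str = "left"
    acpc_distance_mm: float = 24.0
    margin_mm: float = 8.0

    def __post_init__(self):
        if self.geometry not in ("straight", "arc"):
            raise ValidationError(f"unknown geometry {self.geometry!r}")
        if self.noise not in ("none", "gaussian", "rician"):
            raise ValidationError(f"unknown noise model {self.noise!r}")
        if self.noise != "none" and self.snr <= 0:
            raise ValidationError("SNR must be > 0 when noise is enabled")
        extent = min(self.shape) * self.spacing_mm
        if self.geometry == "arc":
            needed = self.arc_radius_mm + 2 * self.bundle_radius_mm + 2 * self.margin_mm
            if needed > extent:
                raise ValidationError(
                    f"arc (radius {self.arc_radius_mm} mm) does not fit the grid"
                )
        if 2 * (self.margin_mm + self.bundle_radius_mm) >= extent:
            raise ValidationError("bundle does not fit inside the grid")


@dataclass
class PhantomData:
    """In-memory phantom: images, ground truth, and auxiliary planning data."""

    spec: PhantomSpec
    dwi: Volume
    truth: TensorField
    rois: ROISet
    atlas: Volume
    landmarks: LandmarkPair
    lesion: Volume
    treatment: pd.DataFrame
    centerline_points: np.ndarray       # (n, 3) world mm, dense polyline
    analytic_length_mm: float

    def centerline_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance (mm) of world points to the bundle centerline."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        d = np.linalg.norm(
            pts[:, None, :] - self.centerline_points[None, :, :], axis=2
        )
        return d.min(axis=1)


def make_scheme(n_directions: int = 56, bval: float = 1200.0) -> DiffusionScheme:
    """One b=0 frame plus ``n_directions`` roughly uniform unit gradients
    (spherical Fibonacci lattice), matching a single-shell acquisition."""
    i = np.arange(n_directions, dtype=float)
    golden = (1 + 5**0.5) / 2
    z = 1 - 2 * (i + 0.5) / n_directions
    phi = 2 * np.pi * i / golden
    r = np.sqrt(np.maximum(1 - z**2, 0.0))
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([[0.0], np.full(n_directions, float(bval))])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dirs])
    return DiffusionScheme(bvals, bvecs)


def _geometry(spec: PhantomSpec, world: np.ndarray):
    """Tangent field, inside-mask and centerline for the requested geometry.

    ``world`` is (..., 3) world mm.  Returns (inside, tangent, centerline
    polyline, analytic length, key centerline points dict).
    """
    extent = np.array(spec.shape) * spec.spacing_mm
    c = (np.array(spec.shape) - 1) / 2.0 * spec.spacing_mm
    if spec.geometry == "straight":
        y0 = spec.margin_mm
        y1 = extent[1] - spec.margin_mm
        radial = np.sqrt((world[..., 0] - c[0]) ** 2 + (world[..., 2] - c[2]) ** 2)
        inside = (
            (radial <= spec.bundle_radius_mm)
            & (world[..., 1] >= y0)
            & (world[..., 1] <= y1)
        )
        tangent = np.zeros(world.shape)
        tangent[..., 1] = 1.0
        ys = np.linspace(y0, y1, 200)
        line = np.column_stack([np.full_like(ys, c[0]), ys, np.full_like(ys, c[2])])
        key = {
            "start": np.array([c[0], y0 + 2.0, c[2]]),
            "mid": np.array([c[0], (y0 + y1) / 2.0, c[2]]),
            "end": np.array([c[0], y1 - 2.0, c[2]]),
            "off": np.array([c[0] + 15.0, (y0 + y1) / 2.0, c[2]]),
        }
        return inside, tangent, line, float(y1 - y0), key

    # quarter-circle arc of radius R in the x-y plane at z = center
    R = spec.arc_radius_mm
    C = np.array([c[0] - R / 2.0, c[1] - R / 2.0, c[2]])
    dx = world[..., 0] - C[0]
    dy = world[..., 1] - C[1]
    dz = world[..., 2] - C[2]
    rho = np.sqrt(dx**2 + dy**2)
    phi = np.arctan2(dy, dx)
    dist = np.sqrt((rho - R) ** 2 + dz**2)
    inside = (dist <= spec.bundle_radius_mm) & (phi >= 0.0) & (phi <= np.pi / 2)
    tangent = np.zeros(world.shape)
    tangent[..., 0] = -np.sin(phi)
    tangent[..., 1] = np.cos(phi)
    phis = np.linspace(0.0, np.pi / 2, 300)
    line = np.column_stack(
        [C[0] + R * np.cos(phis), C[1] + R * np.sin(phis), np.full_like(phis, C[2])]
    )

    def on_arc(a):
        return C + R * np.array([np.cos(a), np.sin(a), 0.0])

    key = {
        "start": on_arc(0.1),
        "mid": on_arc(np.pi / 4),
        "end": on_arc(np.pi / 2 - 0.1),
        "off": C + np.array([0.0, 0.0, 15.0]),
    }
    return inside, tangent, line, float(R * np.pi / 2), key


def _tensor_field(spec: PhantomSpec, inside: np.ndarray, tangent: np.ndarray):
    lam1, lam2, lam3 = spec.eigenvalues
    shape = inside.shape
    D = np.zeros(shape + (3, 3))
    iso = np.eye(3) * spec.background_diffusivity
    D[...] = iso
    t = tangent[inside]
    n = len(t)
    if n:
        # complete an orthonormal frame around the tangent
        helper = np.tile(np.array([0.0, 0.0, 1.0]), (n, 1))
        parallel = np.abs(np.einsum("ij,ij->i", t, helper)) > 0.9
        helper[parallel] = [1.0, 0.0, 0.0]
        e2 = np.cross(t, helper)
        e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
        e3 = np.cross(t, e2)
        Din = (
            lam1 * np.einsum("ni,nj->nij", t, t)
            + lam2 * np.einsum("ni,nj->nij", e2, e2)
            + lam3 * np.einsum("ni,nj->nij", e3, e3)
        )
        D[inside] = Din
    return D


def _sphere_mask(grid_world: np.ndarray, center: np.ndarray, radius_mm: float):
    return np.linalg.norm(grid_world - center, axis=-1) <= radius_mm


def make_phantom(
    spec: PhantomSpec, scheme: Optional[DiffusionScheme] = None
) -> PhantomData:
    """Build a complete synthetic planning dataset; deterministic per seed."""
    if scheme is None:
        scheme = make_scheme()
    rng = np.random.default_rng(spec.seed)
    affine = np.eye(4)
    affine[:3, :3] *= spec.spacing_mm

    idx = np.indices(spec.shape, dtype=float)
    world = np.moveaxis(idx, 0, -1) * spec.spacing_mm

    inside, tangent, line, length, key = _geometry(spec, world)
    D = _tensor_field(spec, inside, tangent)

    # forward Stejskal-Tanner signals
    g = scheme.bvecs
    quad = np.einsum("...ij,kj,ki->...k", D, g, g)  # g^T D g per frame
    signals = spec.s0 * np.exp(-scheme.bvals * quad)
    if spec.noise == "gaussian":
        sigma = spec.s0 / spec.snr
        signals = signals + rng.normal(0.0, sigma, size=signals.shape)
        signals = np.maximum(signals, 1e-3)
    elif spec.noise == "rician":
        sigma = spec.s0 / spec.snr
        n1 = rng.normal(0.0, sigma, size=signals.shape)
        n2 = rng.normal(0.0, sigma, size=signals.shape)
        signals = np.sqrt((signals + n1) ** 2 + n2**2)
    dwi = Volume(signals, affine.copy())

    truth = TensorField(
        tensors=matrices_to_components(D),
        s0=np.full(spec.shape, spec.s0),
        mask=np.ones(spec.shape, dtype=bool),
        affine=affine.copy(),
    )

    roi_r = spec.roi_radius_vox * spec.spacing_mm
    masks = {
        "seed": _sphere_mask(world, key["start"], roi_r),
        "target": _sphere_mask(world, key["end"], roi_r),
        "waypoint": _sphere_mask(world, key["mid"], roi_r),
        "off_corridor": _sphere_mask(world, key["off"], roi_r),
    }
    rois = ROISet({k: Volume(v, affine.copy()) for k, v in masks.items()})

    # two atlas labels split the corridor at its midpoint along y
    atlas_data = np.ones(spec.shape, dtype=np.int16)
    atlas_data[world[..., 1] >= key["mid"][1]] = 2
    atlas = Volume(atlas_data, affine.copy())

    c = (np.array(spec.shape) - 1) / 2.0 * spec.spacing_mm
    half = spec.acpc_distance_mm / 2.0
    landmarks = LandmarkPair(
        ac=c + np.array([0.0, half, 0.0]), pc=c - np.array([0.0, half, 0.0])
    )

    lesion = Volume(_sphere_mask(world, key["mid"], 2.5), affine.copy())

    std = standard_coordinate(landmarks, spec.side)
    # the treatment log lives in AC-PC space (PC at the origin)
    std_acpc = std.point - landmarks.pc
    n_points = 5
    offsets = rng.normal(0.0, 1.0, size=(n_points, 3))
    temps = np.array([57.5, 56.0, 55.0, 55.8, 53.0])
    treatment = pd.DataFrame(
        {
            "patient": ["phantom"] * n_points,
            "x": std_acpc[0] + offsets[:, 0],
            "y": std_acpc[1] + offsets[:, 1],
            "z": std_acpc[2] + offsets[:, 2],
            "temp_c": temps,
        }
    )

    return PhantomData(
        spec=spec,
        dwi=dwi,
        truth=truth,
        rois=rois,
        atlas=atlas,
        landmarks=landmarks,
        lesion=lesion,
        treatment=treatment,
        centerline_points=line,
        analytic_length_mm=length,
    )


def phantom_bundle_specs() -> list:
    """Bundle specs wired to the phantom's ROI names, one per clinical
    bundle so the full plan exercises every iteration contract."""
    return [
        BundleSpec("CTT", "seed", ["waypoint", "target"], [], 100, 2500),
        BundleSpec("PTT", "seed", ["waypoint"], [], 100, 500),
        BundleSpec("CST", "seed", ["target"], ["off_corridor"], 100, 500),
        BundleSpec("ML", "seed", ["waypoint", "target"], [], 100, 500),
    ]


def _synthetic_t1(data: PhantomData) -> Volume:
    """A smooth T1-like anatomical volume (synthetic stand-in)."""
    from scipy import ndimage

    spec = data.spec
    idx = np.indices(spec.shape, dtype=float)
    world = np.moveaxis(idx, 0, -1) * spec.spacing_mm
    c = (np.array(spec.shape) - 1) / 2.0 * spec.spacing_mm
    r = np.linalg.norm((world - c) / (np.array(spec.shape) * spec.spacing_mm / 2.2), axis=-1)
    head = (r <= 1.0).astype(float) * 800.0
    inside, _, _, _, _ = _geometry(spec, world)
    t1 = ndimage.gaussian_filter(head + 200.0 * inside, sigma=2.0)
    return Volume(t1, data.dwi.affine.copy())


def write_phantom_dataset(
    out_dir, spec: Optional[PhantomSpec] = None,
    scheme: Optional[DiffusionScheme] = None,
) -> dict:
    """Emit a phantom as files in the package's external dialects.

    Writes NIfTI volumes, FSL bval/bvec text, landmarks JSON, ROI manifest,
    bundle/parameter configs, the treatment-log CSV, a ready-to-run plan
    config, and a manifest listing every file plus the ground-truth
    parameters.  Returns the manifest dict.
    """
    spec = spec or PhantomSpec()
    scheme = scheme or make_scheme()
    data = make_phantom(spec, scheme)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "rois").mkdir(exist_ok=True)

    files: Dict[str, str] = {}

    def _write_vol(name: str, vol: Volume, dtype=None):
        arr = vol.data if dtype is None else vol.data.astype(dtype)
        save_volume(Volume(arr, vol.affine), out / name)
        files[name.split(".")[0]] = name

    _write_vol("t1.nii", _synthetic_t1(data))
    _write_vol("dwi.nii", data.dwi, np.float32)
    _write_vol("atlas.nii", data.atlas, np.int16)
    _write_vol("lesion.nii", data.lesion, np.uint8)
    save_scheme(scheme, out / "dwi.bval", out / "dwi.bvec")
    files["bval"] = "dwi.bval"
    files["bvec"] = "dwi.bvec"
    save_landmarks(data.landmarks, out / "landmarks.json")
    files["landmarks"] = "landmarks.json"

    roi_entries = {}
    for name in data.rois.names():
        rel = f"rois/{name}.nii"
        save_volume(
            Volume(data.rois[name].data.astype(np.uint8), data.rois[name].affine),
            out / rel,
        )
        roi_entries[name] = f"{name}.nii"
    with open(out / "rois/manifest.json", "w") as fh:
        json.dump({"rois": roi_entries}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["roi_manifest"] = "rois/manifest.json"

    bundles = [
        {
            "name": b.name,
            "seed_roi": b.seed_roi,
            "include_rois": b.include_rois,
            "exclude_rois": b.exclude_rois,
            "min_fibers": b.min_fibers,
            "max_iterations": b.max_iterations,
        }
        for b in phantom_bundle_specs()
    ]
    with open(out / "bundles.json", "w") as fh:
        json.dump(bundles, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["bundles"] = "bundles.json"

    params = {"default": {}, "overrides": {2: {"step_mm": 0.5}}}
    with open(out / "tracking_params.yaml", "w") as fh:
        yaml.safe_dump(params, fh)
    files["parameter_map"] = "tracking_params.yaml"

    data.treatment.to_csv(out / "treatment_log.csv", index=False)
    files["treatment_log"] = "treatment_log.csv"

    plan_cfg = {
        "t1": "t1.nii",
        "dwi": "dwi.nii",
        "bval": "dwi.bval",
        "bvec": "dwi.bvec",
        "roi_manifest": "rois/manifest.json",
        "atlas": "atlas.nii",
        "landmarks": "landmarks.json",
        "bundles": "bundles.json",
        "parameter_map": "tracking_params.yaml",
        "treatment_log": "treatment_log.csv",
        "lesion": "lesion.nii",
        "side": spec.side,
        "seed": spec.seed,
    }
    with open(out / "plan.yaml", "w") as fh:
        yaml.safe_dump(plan_cfg, fh)
    files["plan_config"] = "plan.yaml"

    manifest = {
        "files": files,
        "ground_truth": {
            "geometry": spec.geometry,
            "eigenvalues_mm2_per_s": list(spec.eigenvalues),
            "background_diffusivity_mm2_per_s": spec.background_diffusivity,
            "bundle_radius_mm": spec.bundle_radius_mm,
            "analytic_length_mm": data.analytic_length_mm,
            "s0": spec.s0,
            "noise": spec.noise,
            "snr": spec.snr if spec.noise != "none" else None,
            "seed": spec.seed,
            "side": spec.side,
            "acpc_distance_mm": spec.acpc_distance_mm,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def smooth_blob_volume(
    shape=(48, 48, 48), spacing: float = 1.0, n_blobs: int = 8,
    sigma_mm: float = 5.0, seed: int = 0,
) -> Volume:
    """A band-limited sum-of-Gaussians volume for registration exercises."""
    rng = np.random.default_rng(seed)
    affine = np.eye(4)
    affine[:3, :3] *= spacing
    idx = np.indices(shape, dtype=float)
    world = np.moveaxis(idx, 0, -1) * spacing
    extent = np.array(shape) * spacing
    centers = rng.uniform(0.25, 0.75, size=(n_blobs, 3)) * extent
    amps = rng.uniform(0.5, 1.5, size=n_blobs)
    data = np.zeros(shape)
    for ctr, amp in zip(centers, amps):
        d2 = np.sum((world - ctr) ** 2, axis=-1)
        data += amp * np.exp(-d2 / (2 * sigma_mm**2))
    return Volume(data, affine)
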