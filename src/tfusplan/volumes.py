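"""Core image containers and file I/O.

The world coordinate convention used throughout the package is RAS-like with
+x toward the patient's *left*, +y anterior and +z superior, so the 14 mm
"lateral left" offset of the standard target is +14 on x and the right side
is -14.  Voxel indices are 0-based and voxel *centers* map through the
affine (NIfTI convention).  4D volumes keep the gradient axis last.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, ValidationError, DegenerateLandmarksError

__all__ = [
    "Volume",
    "DiffusionScheme",
    "LandmarkPair",
    "load_volume",
    "save_volume",
    "load_scheme",
    "save_scheme",
    "load_landmarks",
    "save_landmarks",
]


@dataclass
class Volume:
    """A 3D scalar grid (or 4D with trailing gradient/channel axis) plus a
    4x4 affine mapping continuous voxel indices to world millimeters."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError(f"affine must be 4x4, got {self.affine.shape}")
        if self.data.ndim not in (3, 4):
            raise FormatError(f"volume must be 3D or 4D, got {self.data.ndim}D")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is singular")
        if np.any(self.spacing <= 0):
            raise ValidationError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, index) -> np.ndarray:
        """Map continuous voxel indices (..., 3) to world mm."""
        idx = np.asarray(index, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, point) -> np.ndarray:
        """Map world mm points (..., 3) to continuous voxel indices."""
        pts = np.asarray(point, dtype=float)
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def like(self, data: np.ndarray) -> "Volume":
        """A new volume on this grid with different data."""
        return Volume(data, self.affine.copy())


@dataclass
class DiffusionScheme:
    """Gradient table: b-values in s/mm^2 and unit gradient directions.

    ``bvecs`` is stored one row per frame (N, 3); the FSL file dialect
    (3 rows by N columns) is transposed on read/write.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise FormatError(f"bvecs must be (N, 3), got {self.bvecs.shape}")
        if len(self.bvals) != len(self.bvecs):
            raise FormatError(
                f"{len(self.bvals)} b-values but {len(self.bvecs)} gradients"
            )
        if not np.any(self.bvals == 0):
            raise ValidationError("scheme has no b=0 (S0) frame")
        weighted = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[weighted], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValidationError("weighted gradient directions must be unit norm")

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_frames(self) -> int:
        return len(self.bvals)

    @property
    def n_weighted(self) -> int:
        return int(np.count_nonzero(self.bvals > 0))


@dataclass
class LandmarkPair:
    """AC (anterior commissure) and PC (posterior commissure) in world mm."""

    ac: np.ndarray
    pc: np.ndarray

    def __post_init__(self):
        self.ac = np.asarray(self.ac, dtype=float).reshape(3)
        self.pc = np.asarray(self.pc, dtype=float).reshape(3)
        if self.distance == 0:
            raise DegenerateLandmarksError("AC and PC coincide")

    @property
    def distance(self) -> float:
        return float(np.linalg.norm(self.ac - self.pc))


def load_volume(path) -> Volume:
    """Load a NIfTI-1 file (optionally gzipped) without resampling."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # truncated / non-NIfTI files
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    if data.ndim not in (3, 4):
        raise FormatError(f"{path}: expected a 3D or 4D image, got {data.ndim}D")
    return Volume(data, img.affine)


def save_volume(v: Volume, path) -> None:
    """Write a volume as NIfTI-1; round-trips data bit-exactly."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(np.asarray(v.data), v.affine)
    img.set_data_dtype(v.data.dtype)
    img.to_filename(str(path))


def load_scheme(bval_path, bvec_path) -> DiffusionScheme:
    """Read an FSL-style gradient table (bval 1xN, bvec 3xN whitespace text)."""
    try:
        bvals = np.loadtxt(bval_path, ndmin=1).ravel()
        bvecs = np.loadtxt(bvec_path, ndmin=2)
    except OSError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse gradient table: {exc}") from exc
    if bvecs.shape[0] != 3:
        raise FormatError(f"bvec file must have 3 rows, got {bvecs.shape[0]}")
    if bvecs.shape[1] != len(bvals):
        raise FormatError(
            f"{len(bvals)} b-values but {bvecs.shape[1]} gradient columns"
        )
    return DiffusionScheme(bvals, bvecs.T)


def save_scheme(scheme: DiffusionScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.9g")


def load_landmarks(path) -> LandmarkPair:
    """Read landmarks JSON: {"ac": [x,y,z], "pc": [x,y,z]} in world mm."""
    with open(path) as fh:
        obj = json.load(fh)
    try:
        return LandmarkPair(np.asarray(obj["ac"]), np.asarray(obj["pc"]))
    except KeyError as exc:
        raise FormatError(f"landmarks file {path} missing key {exc}") from exc


def save_landmarks(lm: LandmarkPair, path) -> None:
    with open(path, "w") as fh:
        json.dump({"ac": list(lm.ac), "pc": list(lm.pc)}, fh, indent=2, sort_keys=True)
        fh.write("\n")
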