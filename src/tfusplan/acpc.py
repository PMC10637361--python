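"""AC-PC reorientation and the geometric standard target coordinate.

The standard stereotactic target for essential-tremor ablation is defined
relative to the commissures: anterior to the PC by 25% of the AC-PC
distance, 1 mm superior to the AC-PC axial plane, and 14 mm lateral on the
treated side.  Reorientation rotates the head so the commissures share an
axial plane with the AC-PC line running along the anterior (+y) axis; an
optional roll correction about that line can be estimated by rigid
registration against a user-supplied AC-PC-aligned reference volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import DegenerateLandmarksError, ValidationError
from .volumes import LandmarkPair, Volume

__all__ = [
    "RigidTransform",
    "StandardCoordinate",
    "LATERAL_OFFSET_MM",
    "SUPERIOR_OFFSET_MM",
    "ANTERIOR_FRACTION",
    "acpc_transform",
    "reorient_to_acpc",
    "standard_coordinate",
]

#: Lateral offset (mm) of the standard target from the midsagittal plane.
LATERAL_OFFSET_MM = 14.0
#: Superior offset (mm) above the AC-PC axial plane.
SUPERIOR_OFFSET_MM = 1.0
#: Anterior offset from the PC as a fraction of the AC-PC distance.
ANTERIOR_FRACTION = 0.25

#: Minimum plausible AC-PC distance (mm); shorter pairs are degenerate.
MIN_ACPC_DISTANCE_MM = 5.0


@dataclass
class RigidTransform:
    """y = R x + t with R orthonormal, det +1."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-9:
            raise ValidationError(f"rotation not orthonormal (residual {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValidationError("rotation has determinant -1 (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class StandardCoordinate:
    """The standard target point in AC-PC space plus the treated side."""

    point: np.ndarray
    side: str

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")


def _rotation_taking(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix with R @ u == v for unit vectors u, v."""
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-14:
        return np.eye(3)
    if c < -1.0 + 1e-14:
        # 180 degrees: rotate about any axis perpendicular to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, [0.0, 0.0, 1.0])
        axis /= np.linalg.norm(axis)
        return _rodrigues(axis, np.pi)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis = axis / s
    return _rodrigues(axis, np.arctan2(s, c))


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    k = np.asarray(axis, dtype=float)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _check_landmarks(lm: LandmarkPair) -> None:
    if lm.distance < MIN_ACPC_DISTANCE_MM:
        raise DegenerateLandmarksError(
            f"AC-PC distance {lm.distance:.2f} mm < {MIN_ACPC_DISTANCE_MM} mm"
        )


def acpc_transform(
    lm: LandmarkPair,
    roll_reference: Optional[Volume] = None,
    image: Optional[Volume] = None,
) -> RigidTransform:
    """Rigid transform into AC-PC space.

    The rotation takes the PC->AC direction onto +y (anterior), so the
    transformed commissures share both an axial (z) plane and a sagittal
    (x) plane; the translation places the PC at the origin.  If
    ``roll_reference`` is given together with ``image``, the residual roll
    about the AC-PC axis is estimated by rigidly registering the reoriented
    image to the reference and composed in; otherwise roll is 0.
    """
    _check_landmarks(lm)
    u = (lm.ac - lm.pc) / lm.distance
    rot = _rotation_taking(u, np.array([0.0, 1.0, 0.0]))
    base = RigidTransform(rot, -rot @ lm.pc)
    if roll_reference is None:
        return base
    if image is None:
        raise ValidationError("roll estimation needs the image being aligned")
    from .registration import register_rigid  # deferred: avoids heavy import

    spacing = float(np.min(roll_reference.spacing))
    aligned = reorient_to_acpc(image, base, target_spacing=spacing)
    result = register_rigid(roll_reference, aligned, n_levels=3)
    # keep only the roll component (rotation about the +y AC-PC axis); the
    # registration recovers the residual roll of the reoriented image, so
    # its inverse is composed in to undo it
    R = result.transform.rotation
    theta = np.arctan2(R[0, 2] - R[2, 0], R[0, 0] + R[2, 2])
    roll = RigidTransform(_rodrigues(np.array([0.0, 1.0, 0.0]), -theta), np.zeros(3))
    return roll.compose(base)


def reorient_to_acpc(
    v: Volume, t: RigidTransform, target_spacing: float = 1.0
) -> Volume:
    """Resample a 3D volume onto an axis-aligned grid in AC-PC space.

    The output grid covers the transformed bounding box of the input at
    isotropic ``target_spacing``; values are trilinearly interpolated.  The
    same transform can be applied to any derived map (e.g. probability
    maps) by calling this function on it.
    """
    if v.data.ndim != 3:
        raise ValidationError("reorient_to_acpc expects a 3D volume")
    if target_spacing <= 0:
        raise ValidationError("target_spacing must be positive")
    n = np.array(v.spatial_shape, dtype=float)
    corners_vox = np.array(
        [[i, j, k] for i in (-0.5, n[0] - 0.5)
         for j in (-0.5, n[1] - 0.5)
         for k in (-0.5, n[2] - 0.5)]
    )
    corners_world = t.apply(v.voxel_to_world(corners_vox))
    lo = corners_world.min(axis=0)
    hi = corners_world.max(axis=0)
    shape = np.maximum(np.ceil((hi - lo) / target_spacing).astype(int), 1)
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * target_spacing
    affine[:3, 3] = lo + target_spacing / 2.0
    out = Volume(np.zeros(tuple(shape), dtype=float), affine)

    idx = np.indices(tuple(shape), dtype=float).reshape(3, -1).T
    world = out.voxel_to_world(idx)
    src_world = t.inverse().apply(world)
    src_vox = v.world_to_voxel(src_world)
    sampled = ndimage.map_coordinates(
        v.data.astype(float), src_vox.T, order=1, mode="constant", cval=0.0
    )
    out.data[...] = sampled.reshape(tuple(shape))
    return out


def standard_coordinate(lm: LandmarkPair, side: str) -> StandardCoordinate:
    """Standard target from AC-PC-aligned landmarks.

    point = PC + 0.25*|AC-PC| along PC->AC, +1 mm superior, +/-14 mm
    lateral (left is +x under the package convention).
    """
    _check_landmarks(lm)
    if side not in ("left", "right"):
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
    anterior = (lm.ac - lm.pc) / lm.distance
    lateral = LATERAL_OFFSET_MM if side == "left" else -LATERAL_OFFSET_MM
    point = (
        lm.pc
        + ANTERIOR_FRACTION * lm.distance * anterior
        + np.array([lateral, 0.0, SUPERIOR_OFFSET_MM])
    )
    return StandardCoordinate(point, side)
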