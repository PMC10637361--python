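"""DWI preprocessing and diffusion-tensor estimation.

Pipeline order: Lanczos-3 supersampling to an isotropic grid (adds no
information but lets the tracker use plain trilinear interpolation at
sub-voxel steps), Gaussian smoothing in world mm, then a per-voxel
log-linear least-squares solution of the Stejskal-Tanner signal model

    S_k = S0 * exp(-b_k g_k^T D g_k)

for the symmetric diffusion tensor D (mm^2/s).  Derived maps: fractional
anisotropy and the FA-weighted color-coded principal-direction map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import DesignMatrixRankError, ValidationError
from .volumes import DiffusionScheme, Volume, load_volume, save_volume

__all__ = [
    "TensorField",
    "lanczos3_resample",
    "gaussian_smooth",
    "fit_tensors",
    "fa_map",
    "color_direction_map",
    "save_tensorfield",
    "load_tensorfield",
]

#: Lower-triangular component order used for (…, 6) tensor arrays.
TENSOR_COMPONENT_ORDER = ("dxx", "dxy", "dyy", "dxz", "dyz", "dzz")
# indices into a 3x3 matrix for the order above
_TRI = ((0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2))


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors on a grid.

    ``tensors`` holds the 6 unique components (order
    :data:`TENSOR_COMPONENT_ORDER`) in mm^2/s; ``s0`` the non-weighted
    signal; ``mask`` flags voxels where the fit is valid.
    """

    tensors: np.ndarray  # (X, Y, Z, 6)
    s0: np.ndarray       # (X, Y, Z)
    mask: np.ndarray     # (X, Y, Z) bool
    affine: np.ndarray   # 4x4

    def __post_init__(self):
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 4 or self.tensors.shape[-1] != 6:
            raise ValidationError("tensors must have shape (X, Y, Z, 6)")
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def spatial_shape(self) -> tuple:
        return self.tensors.shape[:3]

    def matrices(self) -> np.ndarray:
        """Full symmetric (…, 3, 3) tensor matrices."""
        return components_to_matrices(self.tensors)

    def eigensystem(self):
        """Eigenvalues (descending, clamped at 0) and matching eigenvectors.

        Returns ``(evals, evecs)`` with shapes (…, 3) and (…, 3, 3);
        ``evecs[..., :, i]`` is the eigenvector of ``evals[..., i]``.
        Raw tensors keep any negative eigenvalues; the clamping applies
        only to these derived quantities.
        """
        w, v = np.linalg.eigh(self.matrices())
        order = np.argsort(w, axis=-1)[..., ::-1]
        w = np.take_along_axis(w, order, axis=-1)
        v = np.take_along_axis(v, order[..., None, :], axis=-1)
        w = np.clip(w, 0.0, None)
        w[~self.mask] = 0.0
        return w, v

    def grid(self) -> Volume:
        return Volume(self.s0, self.affine)


def components_to_matrices(c6: np.ndarray) -> np.ndarray:
    c6 = np.asarray(c6, dtype=float)
    out = np.zeros(c6.shape[:-1] + (3, 3))
    for k, (i, j) in enumerate(_TRI):
        out[..., i, j] = c6[..., k]
        out[..., j, i] = c6[..., k]
    return out


def matrices_to_components(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    return np.stack([m[..., i, j] for (i, j) in _TRI], axis=-1)


def lanczos3_kernel(x) -> np.ndarray:
    """L(x) = sinc(x) sinc(x/3) for |x| < 3, else 0 (np.sinc is normalized)."""
    x = np.asarray(x, dtype=float)
    return np.where(np.abs(x) < 3.0, np.sinc(x) * np.sinc(x / 3.0), 0.0)


def _axis_resample_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense (n_out, n_in) Lanczos-3 interpolation matrix along one axis.

    Output sample j sits at input index (j + 0.5)*s - 0.5 with
    s = n_in / n_out, preserving the world extent of the axis.  Edge
    samples clamp to the boundary; weights are renormalized to sum to 1
    so a constant signal is reproduced exactly.
    """
    s = n_in / n_out
    W = np.zeros((n_out, n_in))
    for j in range(n_out):
        x = (j + 0.5) * s - 0.5
        k0 = int(np.ceil(x - 3.0))
        ks = np.arange(k0, int(np.floor(x + 3.0)) + 1)
        w = lanczos3_kernel(x - ks)
        ks = np.clip(ks, 0, n_in - 1)
        np.add.at(W[j], ks, w)
        W[j] /= W[j].sum()
    return W


def lanczos3_resample(v: Volume, target_spacing: float) -> Volume:
    """Separable Lanczos-3 resampling to an isotropic spatial grid.

    World extent is preserved: the output voxel count per axis is
    ``round(extent / target_spacing)`` and the affine is updated so output
    voxel centers interleave the old grid.  4D volumes are resampled
    frame by frame along the spatial axes only.
    """
    if target_spacing <= 0:
        raise ValidationError("target_spacing must be positive")
    data = v.data.astype(float)
    n_in = v.spatial_shape
    spacing = v.spacing
    scale = np.ones(3)
    offset = np.zeros(3)
    for ax in range(3):
        extent = n_in[ax] * spacing[ax]
        n_out = max(int(round(extent / target_spacing)), 1)
        W = _axis_resample_matrix(n_in[ax], n_out)
        data = np.moveaxis(np.tensordot(W, np.moveaxis(data, ax, 0), axes=1), 0, ax)
        s = n_in[ax] / n_out
        scale[ax] = s
        offset[ax] = 0.5 * s - 0.5
    T = np.eye(4)
    T[:3, :3] = np.diag(scale)
    T[:3, 3] = offset
    return Volume(data, v.affine @ T)


def gaussian_smooth(v: Volume, sigma_mm: float) -> Volume:
    """Separable Gaussian smoothing with sigma given in world mm."""
    if sigma_mm < 0:
        raise ValidationError("sigma must be >= 0")
    if sigma_mm == 0:
        return Volume(v.data.copy(), v.affine.copy())
    sig_vox = sigma_mm / v.spacing
    if v.data.ndim == 4:
        sig = tuple(sig_vox) + (0.0,)
    else:
        sig = tuple(sig_vox)
    return Volume(ndimage.gaussian_filter(v.data.astype(float), sigma=sig), v.affine)


def _design_matrix(scheme: DiffusionScheme) -> np.ndarray:
    w = scheme.bvals > 0
    g = scheme.bvecs[w]
    b = scheme.bvals[w]
    B = np.column_stack(
        [
            g[:, 0] ** 2,
            2 * g[:, 0] * g[:, 1],
            g[:, 1] ** 2,
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
            g[:, 2] ** 2,
        ]
    )
    return b[:, None] * B


def fit_tensors(
    dwi: Volume, scheme: DiffusionScheme, mask: Optional[Volume] = None
) -> TensorField:
    """Log-linear Stejskal-Tanner tensor fit.

    Per voxel solves ``log(S_k / S0) = -b_k g_k^T D g_k`` by least squares
    over the weighted frames; S0 is the mean of the b=0 frames.  Voxels
    with non-positive S0 or any non-positive weighted signal are masked
    out (their tensor is zero).
    """
    if dwi.data.ndim != 4:
        raise ValidationError("fit_tensors expects a 4D DWI volume")
    if dwi.data.shape[3] != scheme.n_frames:
        raise ValidationError(
            f"DWI has {dwi.data.shape[3]} frames but scheme lists {scheme.n_frames}"
        )
    if scheme.n_weighted < 6:
        raise DesignMatrixRankError(
            f"need >= 6 weighted directions, got {scheme.n_weighted}"
        )
    B = _design_matrix(scheme)
    if np.linalg.matrix_rank(B) < 6:
        raise DesignMatrixRankError("gradient directions do not span 6 tensor dofs")

    data = dwi.data.astype(float)
    s0 = data[..., scheme.b0_mask].mean(axis=-1)
    S = data[..., ~scheme.b0_mask]

    valid = (s0 > 0) & np.all(S > 0, axis=-1)
    if mask is not None:
        valid &= np.asarray(mask.data, dtype=bool)

    shape = dwi.spatial_shape
    tensors = np.zeros(shape + (6,))
    if np.any(valid):
        y = -np.log(S[valid] / s0[valid, None])  # (nvox, nw)
        pinv = np.linalg.pinv(B)                 # (6, nw)
        tensors[valid] = y @ pinv.T
    return TensorField(tensors=tensors, s0=s0, mask=valid, affine=dwi.affine.copy())


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lam - mean(lam)|| / ||lam||, 0 where ||lam|| = 0."""
    lam = np.asarray(evals, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - mean, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def fa_map(tf: TensorField) -> Volume:
    """Fractional anisotropy volume; 0 on masked-out voxels."""
    evals, _ = tf.eigensystem()
    return Volume(fa_from_eigenvalues(evals), tf.affine.copy())


def color_direction_map(tf: TensorField) -> Volume:
    """FA-weighted |e1| color map, 3 channels in [0, 1]."""
    evals, evecs = tf.eigensystem()
    fa = fa_from_eigenvalues(evals)
    rgb = np.abs(evecs[..., :, 0]) * fa[..., None]
    rgb[~tf.mask] = 0.0
    return Volume(np.clip(rgb, 0.0, 1.0), tf.affine.copy())


def save_tensorfield(tf: TensorField, path) -> None:
    """Persist as a 6-component 4D NIfTI plus a sidecar JSON naming the order."""
    path = Path(path)
    save_volume(Volume(tf.tensors, tf.affine), path)
    base = str(path)
    for suffix in (".nii.gz", ".nii"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            break
    side = {
        "component_order": list(TENSOR_COMPONENT_ORDER),
        "units": "mm^2/s",
    }
    with open(base + ".json", "w") as fh:
        json.dump(side, fh, indent=2, sort_keys=True)
        fh.write("\n")
    save_volume(Volume(tf.s0[..., None], tf.affine), base + "_s0.nii")
    save_volume(Volume(tf.mask.astype(np.uint8)[..., None], tf.affine), base + "_mask.nii")


def load_tensorfield(path) -> TensorField:
    path = Path(path)
    vol = load_volume(path)
    base = str(path)
    for suffix in (".nii.gz", ".nii"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            break
    with open(base + ".json") as fh:
        side = json.load(fh)
    if list(side.get("component_order", [])) != list(TENSOR_COMPONENT_ORDER):
        raise ValidationError("unexpected tensor component order in sidecar")
    s0 = load_volume(base + "_s0.nii").data[..., 0]
    mask = load_volume(base + "_mask.nii").data[..., 0].astype(bool)
    return TensorField(vol.data, s0, mask, vol.affine)
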