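"""Bundle definitions, ROI role semantics, and region-adaptive parameters.

Four bundles matter for essential-tremor planning: the cerebellothalamic
(CTT) and pallidothalamic (PTT) target tracts and the corticospinal tract
(CST) / medial lemniscus (ML) no-go tracts.  Each bundle is constrained by
a seed ROI (where streamlines start), include ROIs (all must be
traversed) and exclude ROIs (none may be touched).  Tracking parameters
can be overridden per atlas label so the tracker adapts locally to white
matter regions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List

import numpy as np
import yaml

from .errors import ValidationError
from .volumes import Volume, load_volume

__all__ = [
    "ROISet",
    "BundleSpec",
    "TrackingParameters",
    "RegionParameterMap",
    "BUNDLE_NAMES",
    "default_bundle_specs",
    "default_parameter_map",
    "params_at",
    "validate_roiset",
    "load_roiset",
    "load_bundle_specs",
    "load_parameter_map",
]

logger = logging.getLogger(__name__)

BUNDLE_NAMES = ("CTT", "PTT", "CST", "ML")

#: Minimum accepted streamlines before a bundle's retry loop may stop.
DEFAULT_MIN_FIBERS = 100
#: Iteration cap for the retry loop; the CTT gets an extended cap because
#: threading both the small red nucleus and the thalamus is hard.
DEFAULT_MAX_ITERATIONS = 500
CTT_MAX_ITERATIONS = 2500


@dataclass
class BundleSpec:
    """A named tract with its ROI roles and iteration contract."""

    name: str
    seed_roi: str
    include_rois: List[str] = field(default_factory=list)
    exclude_rois: List[str] = field(default_factory=list)
    min_fibers: int = DEFAULT_MIN_FIBERS
    max_iterations: int = DEFAULT_MAX_ITERATIONS

    def __post_init__(self):
        if self.min_fibers < 1:
            raise ValidationError("min_fibers must be >= 1")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if self.seed_roi in self.exclude_rois:
            raise ValidationError(f"{self.name}: seed ROI is also an exclude ROI")


@dataclass
class ROISet:
    """Named binary masks sharing one grid; laterality is encoded in the
    name suffix (``_left`` / ``_right``)."""

    masks: Dict[str, Volume]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> Volume:
        return self.masks[name]

    def names(self) -> List[str]:
        return sorted(self.masks)


@dataclass
class TrackingParameters:
    """Streamline integration parameters; see the parameter map for the
    per-atlas-region override mechanism."""

    step_mm: float = 1.0
    fa_threshold: float = 0.15
    max_angle_deg: float = 45.0
    min_length_mm: float = 20.0
    max_length_mm: float = 200.0

    def __post_init__(self):
        if self.step_mm <= 0:
            raise ValidationError("step_mm must be > 0")
        if not (0 <= self.fa_threshold < 1):
            raise ValidationError("fa_threshold must be in [0, 1)")
        if not (0 < self.max_angle_deg <= 90):
            raise ValidationError("max_angle_deg must be in (0, 90]")
        if self.min_length_mm >= self.max_length_mm:
            raise ValidationError("min_length_mm must be < max_length_mm")


@dataclass
class RegionParameterMap:
    """Default tracking parameters plus partial overrides keyed by atlas
    label id.  Lookups are nearest-voxel on the label grid; labels are
    never interpolated."""

    default: TrackingParameters = field(default_factory=TrackingParameters)
    overrides: Dict[int, dict] = field(default_factory=dict)

    def resolve(self, label: int) -> TrackingParameters:
        ov = self.overrides.get(int(label))
        if not ov:
            return self.default
        return replace(self.default, **ov)


def default_parameter_map() -> RegionParameterMap:
    return RegionParameterMap()


def _side_names(side: str):
    if side not in ("left", "right"):
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
    ipsi = side
    contra = "right" if side == "left" else "left"
    return ipsi, contra


def default_bundle_specs(side: str) -> List[BundleSpec]:
    """The four planning bundles for a treated side.

    Laterality: the treated side is ipsilateral.  The CTT decussates, so
    its cerebellar ROIs (dentate nucleus, superior cerebellar peduncle)
    are contralateral while red nucleus and thalamus are ipsilateral; its
    seed is the precentral gyrus on the treated side.
    """
    ipsi, contra = _side_names(side)
    return [
        BundleSpec(
            name="CTT",
            seed_roi=f"precentral_gyrus_{ipsi}",
            include_rois=[
                f"dentate_nucleus_{contra}",
                f"superior_cerebellar_peduncle_{contra}",
                f"red_nucleus_{ipsi}",
                f"thalamus_{ipsi}",
            ],
            max_iterations=CTT_MAX_ITERATIONS,
        ),
        BundleSpec(
            name="PTT",
            seed_roi=f"globus_pallidus_interna_{ipsi}",
            include_rois=[f"frontal_thalamus_{ipsi}"],
        ),
        BundleSpec(
            name="CST",
            seed_roi=f"precentral_gyrus_{ipsi}",
            include_rois=[
                f"cerebral_peduncle_{ipsi}",
                f"posterior_limb_internal_capsule_{ipsi}",
            ],
            exclude_rois=[f"thalamus_{ipsi}"],
        ),
        BundleSpec(
            name="ML",
            seed_roi=f"ml_midbrain_{ipsi}",
            include_rois=[
                f"postcentral_gyrus_{ipsi}",
                f"thalamus_{ipsi}",
            ],
        ),
    ]


def params_at(
    pm: RegionParameterMap, atlas: Volume, point
) -> TrackingParameters:
    """Tracking parameters at a world-mm point via nearest-voxel atlas lookup."""
    vox = np.rint(atlas.world_to_voxel(np.asarray(point, dtype=float))).astype(int)
    shape = np.array(atlas.spatial_shape)
    if np.any(vox < 0) or np.any(vox >= shape):
        logger.warning("point %s outside atlas bounding box; using defaults", point)
        return pm.default
    label = int(atlas.data[tuple(vox)])
    return pm.resolve(label)


@dataclass
class RoiViolation:
    bundle: str
    roi: str
    role: str
    problem: str
    fatal: bool


def validate_roiset(rs: ROISet, specs: List[BundleSpec]) -> List[RoiViolation]:
    """Check every ROI referenced by the specs exists, is non-empty where it
    must be, and shares the common grid.  Returns a violation report
    (empty when everything is consistent); never raises."""
    report: List[RoiViolation] = []
    ref_affine = None
    ref_shape = None
    for name, vol in rs.masks.items():
        if ref_affine is None:
            ref_affine = vol.affine
            ref_shape = vol.spatial_shape
        elif (
            vol.spatial_shape != ref_shape
            or not np.allclose(vol.affine, ref_affine, atol=1e-6)
        ):
            report.append(RoiViolation("-", name, "-", "not on common grid", True))
    for spec in specs:
        roles = [(spec.seed_roi, "seed")]
        roles += [(n, "include") for n in spec.include_rois]
        roles += [(n, "exclude") for n in spec.exclude_rois]
        for roi, role in roles:
            if roi not in rs:
                report.append(RoiViolation(spec.name, roi, role, "missing", True))
                continue
            if not np.any(rs[roi].data):
                fatal = role == "seed"
                report.append(
                    RoiViolation(spec.name, roi, role, "empty mask", fatal)
                )
    return report


def load_roiset(manifest_path) -> ROISet:
    """Load masks from a manifest JSON: {"rois": {name: relative path}}."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    masks = {}
    for name, rel in manifest["rois"].items():
        vol = load_volume(manifest_path.parent / rel)
        masks[name] = Volume(vol.data.astype(bool), vol.affine)
    return ROISet(masks)


def load_bundle_specs(path) -> List[BundleSpec]:
    """Bundle specs from YAML/JSON: a list of BundleSpec field mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [BundleSpec(**entry) for entry in raw]


def load_parameter_map(path) -> RegionParameterMap:
    """Parameter map from YAML/JSON with keys ``default`` and ``overrides``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    default = TrackingParameters(**raw.get("default", {}))
    overrides = {int(k): dict(v) for k, v in (raw.get("overrides") or {}).items()}
    return RegionParameterMap(default=default, overrides=overrides)
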