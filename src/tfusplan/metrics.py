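"""Treatment-distance evaluation statistics.

Pure functions over treatment records, probability maps and masks: the
per-patient mean deviation of therapeutic sonication points from the
standard coordinate, its lateral-component variant, conditional cohort
means, point-to-bundle border distances, lesion centroids, and Dice
overlap.  The treatment-log dialect is a CSV with columns
``patient,x,y,z,temp_c`` (world mm, AC-PC space).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List

import numpy as np
import pandas as pd

from .acpc import LATERAL_OFFSET_MM, StandardCoordinate
from .errors import (
    EmptyBundleError,
    EmptyMaskError,
    EmptyRecordError,
    EmptySelectionError,
    UndefinedDiceError,
    ValidationError,
)
from .tracking import ProbabilityMap
from .volumes import Volume

__all__ = [
    "TreatmentRecord",
    "CohortSelection",
    "THERAPEUTIC_TEMP_C",
    "filter_treatment_points",
    "dev",
    "xdev",
    "conditional_mean_dev",
    "point_to_bundle_distance",
    "lesion_center",
    "dice",
    "load_treatment_log",
    "evaluation_report",
]

#: Sonications reaching at least this maximum average temperature (deg C)
#: are considered therapeutic; cooler test pulses are discarded.
THERAPEUTIC_TEMP_C = 55.0


@dataclass
class TreatmentRecord:
    """Therapeutic treatment points of one patient plus the computed
    standard coordinate, all in AC-PC world mm."""

    patient: str
    points: np.ndarray  # (K, 3)
    std_coord: StandardCoordinate

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 1:
            raise EmptyRecordError(f"patient {self.patient}: no treatment points")


@dataclass
class CohortSelection:
    """N records and a predicate on the per-patient deviation; M is the
    number of records satisfying it."""

    records: List[TreatmentRecord]
    condition: Callable[[float], bool]

    @property
    def n(self) -> int:
        return len(self.records)


def filter_treatment_points(
    points, temperatures, threshold: float = THERAPEUTIC_TEMP_C
) -> np.ndarray:
    """Keep points whose temperature reached the threshold (inclusive)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    temps = np.asarray(temperatures, dtype=float).ravel()
    if len(pts) != len(temps):
        raise ValidationError("points and temperatures differ in length")
    keep = temps >= threshold
    if not np.any(keep):
        raise EmptyRecordError(
            f"no treatment point reached {threshold} deg C"
        )
    return pts[keep]


def dev(r: TreatmentRecord) -> float:
    """Mean Euclidean distance (mm) of the points to the standard coordinate."""
    return float(np.mean(np.linalg.norm(r.points - r.std_coord.point, axis=1)))


def xdev(r: TreatmentRecord) -> float:
    """Mean lateral deviation (mm): | |p_x| - 14 | averaged over points.

    The magnitude of the lateral component is used so left- and
    right-side treatments share one formula; the 14 is the lateral offset
    of the standard-coordinate rule, not a free parameter.
    """
    return float(np.mean(np.abs(np.abs(r.points[:, 0]) - LATERAL_OFFSET_MM)))


def conditional_mean_dev(c: CohortSelection, which: str = "dev") -> float:
    """Cohort mean of the per-patient statistic over records satisfying the
    condition: (1/M) * sum of dev(j) (or xdev(j)) for the M selected j."""
    stat = {"dev": dev, "xdev": xdev}.get(which)
    if stat is None:
        raise ValidationError(f"which must be 'dev' or 'xdev', got {which!r}")
    values = [stat(r) for r in c.records]
    selected = [v for v in values if c.condition(v)]
    if not selected:
        raise EmptySelectionError("condition selects no patients (M == 0)")
    return float(np.mean(selected))


def _suprathreshold_centers(p: ProbabilityMap):
    vox = np.argwhere(p.volume.data > 0)
    if len(vox) == 0:
        raise EmptyBundleError("probability map has no suprathreshold voxels")
    return vox, p.volume.voxel_to_world(vox)


def point_to_bundle_distance(point, p: ProbabilityMap) -> float:
    """Distance (mm) from a point to the border of a thresholded bundle.

    0 if the point lies inside a suprathreshold voxel, else the minimum
    Euclidean distance to the suprathreshold voxel centers.
    """
    pt = np.asarray(point, dtype=float).reshape(3)
    vox, centers = _suprathreshold_centers(p)
    nearest = np.rint(p.volume.world_to_voxel(pt)).astype(int)
    shape = np.array(p.volume.spatial_shape)
    if np.all(nearest >= 0) and np.all(nearest < shape):
        if p.volume.data[tuple(nearest)] > 0:
            return 0.0
    return float(np.min(np.linalg.norm(centers - pt, axis=1)))


def lesion_center(mask: Volume) -> np.ndarray:
    """Centroid (world mm) of the masked-in voxel centers."""
    vox = np.argwhere(mask.data)
    if len(vox) == 0:
        raise EmptyMaskError("lesion mask is empty")
    return mask.voxel_to_world(vox).mean(axis=0)


def dice(a: Volume, b: Volume) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two masks on a common grid."""
    if a.spatial_shape != b.spatial_shape:
        raise ValidationError("masks are not on a common grid")
    am = np.asarray(a.data, dtype=bool)
    bm = np.asarray(b.data, dtype=bool)
    denom = am.sum() + bm.sum()
    if denom == 0:
        raise UndefinedDiceError("Dice of two empty masks is undefined")
    return float(2.0 * np.logical_and(am, bm).sum() / denom)


def load_treatment_log(path) -> pd.DataFrame:
    """Read the treatment-log CSV (columns patient, x, y, z, temp_c)."""
    df = pd.read_csv(path)
    required = {"patient", "x", "y", "z", "temp_c"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"treatment log missing columns: {sorted(missing)}")
    return df


def evaluation_report(
    bundle_maps: Dict[str, ProbabilityMap],
    std_coord: StandardCoordinate,
    treatment_points: np.ndarray,
    lesion_mask: Volume = None,
) -> dict:
    """Per-bundle distances to the lesion center, the mean treatment point,
    and the standard coordinate, plus the treatment-deviation statistics."""
    record = TreatmentRecord("run", treatment_points, std_coord)
    mean_point = record.points.mean(axis=0)
    report: dict = {
        "dev_mm": dev(record),
        "xdev_mm": xdev(record),
        "n_treatment_points": int(len(record.points)),
        "bundles": {},
    }
    center = lesion_center(lesion_mask) if lesion_mask is not None else None
    for name, pmap in sorted(bundle_maps.items()):
        entry = {
            "to_standard_coordinate_mm": point_to_bundle_distance(
                std_coord.point, pmap
            ),
            "to_mean_treatment_point_mm": point_to_bundle_distance(mean_point, pmap),
        }
        if center is not None:
            entry["to_lesion_center_mm"] = point_to_bundle_distance(center, pmap)
        report["bundles"][name] = entry
    if center is not None:
        report["lesion_center_mm"] = [float(v) for v in center]
    return report


def format_report_table(report: dict) -> str:
    """Human-readable table mirroring the per-bundle distance rows."""
    lines = [
        f"dev  = {report['dev_mm']:.2f} mm   "
        f"xdev = {report['xdev_mm']:.2f} mm   "
        f"(K = {report['n_treatment_points']} therapeutic points)",
        "",
        f"{'bundle':<8}{'std coord':>12}{'mean treat':>12}{'lesion':>12}",
    ]
    for name, entry in report["bundles"].items():
        lesion = entry.get("to_lesion_center_mm")
        lines.append(
            f"{name:<8}"
            f"{entry['to_standard_coordinate_mm']:>12.2f}"
            f"{entry['to_mean_treatment_point_mm']:>12.2f}"
            f"{(f'{lesion:.2f}' if lesion is not None else '-'):>12}"
        )
    return "\n".join(lines)
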