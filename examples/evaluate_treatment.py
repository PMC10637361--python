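"""Treatment-distance statistics from a treatment log.

Filters sonication points to therapeutic ones (max average temperature
of at least 55 C), then computes the per-patient deviation from the
standard coordinate (dev), its lateral component (xdev), and conditional
cohort means.
"""

import numpy as np

from tfusplan.acpc import StandardCoordinate
from tfusplan.metrics import (
    CohortSelection,
    TreatmentRecord,
    conditional_mean_dev,
    dev,
    filter_treatment_points,
    xdev,
)

std = StandardCoordinate([14.0, 6.0, 1.0], "left")
rng = np.random.default_rng(0)

records = []
for j in range(8):
    raw = std.point + rng.normal(0, 1.2, size=(6, 3))
    temps = rng.uniform(52, 60, size=6)
    pts = filter_treatment_points(raw, temps)      # inclusive >= 55 C
    records.append(TreatmentRecord(f"patient{j}", pts, std))

print(f"{'patient':<10}{'K':>3}{'dev (mm)':>10}{'xdev (mm)':>11}")
for r in records:
    print(f"{r.patient:<10}{len(r.points):>3}{dev(r):>10.2f}{xdev(r):>11.2f}")

cohort_ge2 = CohortSelection(records, lambda d: d >= 2.0)
cohort_lt2 = CohortSelection(records, lambda d: d < 2.0)
print(f"\nmean dev | dev >= 2 mm: {conditional_mean_dev(cohort_ge2):.2f} mm")
print(f"mean dev | dev <  2 mm: {conditional_mean_dev(cohort_lt2):.2f} mm")

# dev measures how far the delivered sonications sat from the geometric
# target; xdev isolates the lateral (medial/lateral) component, the axis
# along which the VIM target is most sensitive.
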