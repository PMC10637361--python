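"""Compute the stereotactic standard target from AC/PC landmarks.

The target rule: 25% of the AC-PC distance anterior to the PC, 1 mm
superior to the AC-PC plane, 14 mm lateral on the treated side.
"""

from tfusplan import LandmarkPair, standard_coordinate

lm = LandmarkPair(ac=[0.0, 26.0, 0.0], pc=[0.0, 0.0, 0.0])  # AC-PC aligned, mm
print(f"AC-PC distance: {lm.distance:.1f} mm")
for side in ("left", "right"):
    std = standard_coordinate(lm, side)
    x, y, z = std.point
    print(f"{side:>5}: ({x:+.1f}, {y:+.1f}, {z:+.1f}) mm")

# The y component is 26 * 0.25 = 6.5 mm anterior of the PC; the x component
# flips sign with the treated side (+x is the patient's left); z is always
# +1 mm above the commissural plane.
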