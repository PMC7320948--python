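"""Score a single patient's CT-angiography grading sheet.

Builds a sheet for a patient with an isolated left M1 occlusion (everything
else normal, good pial collaterals) and prints the score breakdown.  The
whole-brain score drops from the 56-point ceiling to 36 because the M1
segment carries the largest proximal weight (4) and left+right are summed:
the left M1 going from 1 to -4 costs 4 x 5 = 20 points.
"""

from collatscore import (
    PatientVasculature,
    PialCounts,
    Side,
    Vessel,
    pial_only_score,
    whole_brain_score,
)
from collatscore.grading import SLOTS

grades = {(v, s): 1 for v, s in SLOTS}  # all vessels normal / assessable
grades[(Vessel.M1, Side.LEFT)] = -4  # occluded left M1

sheet = PatientVasculature.from_mapping(grades, PialCounts(cortical_count=12, cerebellar_count=3))
breakdown = whole_brain_score(sheet)

print("component contributions:")
for name, value in breakdown.components.items():
    print(f"  {name:>15}: {value:+d}")
print(f"whole-brain collateral score: {breakdown.whole_brain_score}")
print(f"pial-only collateral score:   {pial_only_score(sheet)} (of 4)")
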