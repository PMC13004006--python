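"""Score a single patient's pre-induction assessment.

Builds one ultrasound assessment and one digital (Bishop) examination,
computes both scores, and prints the component breakdown.
"""

from iolscore import (
    BishopAssessment,
    UltrasoundAssessment,
    bishop_score,
    composite_score,
)

# a moderately favorable cervix: short-ish, transverse head, mid-range
# engagement, soft inner cervix, wide angles
us = UltrasoundAssessment(
    cervical_length=15.0,          # mm
    head_position="occiput_transverse",
    head_perineum_distance=45.0,   # mm
    stiffness_inner=12.0,          # kPa
    stiffness_middle=7.0,
    stiffness_outer=4.0,
    anterior_angle=95.0,           # degrees
    posterior_angle=85.0,
)
result = composite_score(us)
print("Composite ultrasound induction score")
print(f"  cervical length  : {result.sub_cl}")
print(f"  head position    : {result.sub_position}")
print(f"  head-perineum    : {result.sub_hpd}")
print(f"  elastography     : {result.sub_elasto}")
print(f"  angulation       : {result.sub_angle}")
print(f"  total            : {result.total} / 10  -> {result.category.value}")

exam = BishopAssessment(dilatation_cm=3, effacement_pct=60, station=-1,
                        consistency="medium", position="mid")
print(f"Bishop score       : {bishop_score(exam)} / 13")
# Each 0-2 sub-score counts toward a 0-10 total banded as low (0-3),
# intermediate (4-6) or high (7-10) probability of vaginal delivery.
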