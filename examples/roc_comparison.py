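"""Compare the composite score and the Bishop score on one cohort.

Simulates a 200-woman cohort, evaluates both scores against the vaginal-
delivery outcome with nonparametric ROC analysis, and runs the DeLong
paired test on the AUC difference.
"""

import numpy as np

from iolscore import (
    CohortConfig,
    bishop_score,
    compare_paired_auc,
    composite_score,
    generate_cohort,
    roc_curve,
)

records = generate_cohort(CohortConfig(), seed=2024)
composite = np.array([composite_score(r.ultrasound).total for r in records])
bishop = np.array([bishop_score(r.bishop) for r in records])
outcome = np.array([r.outcome == "vaginal_delivery" for r in records], float)

for name, scores in (("composite", composite), ("Bishop", bishop)):
    c = roc_curve(scores, outcome)
    print(f"{name:>9} score: AUC {c.auc:.3f} (SE {c.se:.3f}, "
          f"95% CI {c.ci_low:.3f}-{c.ci_high:.3f}, p vs 0.5 = {c.p_vs_half:.2g})")

paired = compare_paired_auc(bishop, composite, outcome)
print(f"paired AUC difference (composite - Bishop): {paired.delta:+.3f}, "
      f"p = {paired.p_value:.3f}")

# a few cutoff coordinates of the composite-score curve
c = roc_curve(composite, outcome)
print("\ncutoff  sensitivity  1-specificity")
for p in c.points[3:8]:
    print(f"{p.cutoff:>5.1f}  {p.sensitivity:>11.3f}  {p.one_minus_specificity:>13.3f}")
# AUC is the probability a random vaginal delivery outranks a random
# cesarean; the cutoff table shows the sensitivity/false-positive
# trade-off for 'score >= cutoff' decision rules.
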