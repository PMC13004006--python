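"""Run the complete analysis pipeline on a simulated cohort.

Simulates the default 200-woman cohort, then produces the full report:
cohort summary, per-score ROC analysis, DeLong paired comparison,
parity-stratified curves and the age-adjusted logistic model.
Equivalent shell command:  iolscore report --seed 11
"""

from iolscore import CohortConfig, run_pipeline

report = run_pipeline(config=CohortConfig(), seed=11)
print(report.to_text())

# the same report as machine-readable JSON:
# print(report.to_json())
# The adjusted odds ratio for `composite_score` is per unit of the 0-10
# total, holding maternal age fixed.
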