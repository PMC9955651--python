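"""Cohort-level repeated-measures statistics.

Generates a small paced-breathing cohort, evaluates the measure battery
on every trial, selects each subject's resonance rate, and runs the
Friedman / Conover / direction-count pipeline for a few measures.
Large chi-square and Kendall's W mean a measure separates the breathing
trials; a consistent direction count means nearly everyone moved the
same way between Baseline and resonance breathing.
"""

from hrvcomplexity import pipeline
from hrvcomplexity.synth import CohortSpec, gen_cohort

cohort = gen_cohort(CohortSpec(n_subjects=16, seed=5))
labels = pipeline.select_rbr_labels(cohort)
table = pipeline.cohort_table(cohort, rbr_labels=labels)
print(f"{len(table)} measure values "
      f"({len(cohort)} subjects x 8 trials x {len(pipeline.MEASURES)} "
      f"measures)\n")

for measure in ("SD1", "FD_H", "CPEI", "GI"):
    out = pipeline.trial_statistics(table, measure)
    fr = out["friedman"]
    d = out["direction"]
    top = max(zip(out["conover"].standardized, out["conover"].pairs))
    print(f"{measure:>6}: chi2 = {fr.chi2:7.2f}  W = {fr.kendall_w:.3f}  "
          f"p = {fr.p:.2e}  | Baseline->RBR ups = {d['ups']:2d}/16 "
          f"consistent = {d['consistent']}  | top pair {top[1]}")

print("\nSD1 (vagally mediated short-term variability) rises at resonance")
print("for nearly all subjects; entropy-type measures fall as the RR")
print("series becomes dominated by one oscillation.")
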