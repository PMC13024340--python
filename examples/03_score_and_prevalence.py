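"""Score a symptomatic-style cohort and tabulate abnormality prevalence.

Every segment gets the three regression-based indices (TI/AVI/PVI: the
observed translation or disc opening minus its rotation-predicted value,
divided by the forecast standard error; |index| <= 2 is within normal
limits), the standardized disc height, and the classical criteria
(adjacent-level rotation or flexion segment-angle difference > 11 deg,
|translation| > 20 %EPW).  Segments rotating < 5 deg are excluded as
insufficiently stressed.  The effort filter then restricts to exams whose
total C2-C7 rotation exceeds 60 deg - prevalence typically rises, because
an under-stressed spine hides abnormalities.
"""

import ivmetrics as ivm
from ivmetrics.scoring import effort_filter, prevalence

reference = ivm.fit_reference(
    ivm.generate_metric_cohort(ivm.GeneratorConfig(n_subjects=400, seed=0))
)

# a lower-effort cohort, as seen in symptomatic patients
patients = ivm.generate_metric_cohort(
    ivm.GeneratorConfig(n_subjects=300, seed=42, effort=0.8)
)
scored = ivm.score_records(patients, reference)

print("prevalence, all analyzable segments (percent abnormal):")
print(prevalence(scored).round(1).to_string(index=False))

adequate = effort_filter(scored, min_total_rotation=60.0)
n_before = scored["exam_id"].nunique()
n_after = adequate["exam_id"].nunique()
print(f"\nafter the >60 deg effort filter ({n_after}/{n_before} exams retained):")
print(prevalence(adequate).round(1).to_string(index=False))
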