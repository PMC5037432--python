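"""Sensitivity re-analysis: drop HWE-violating and non-white studies.

Builds a five-study dataset in which one study both violates HWE in
controls (no heterozygotes at all) and comes from a different source
population, then compares the pooled effects with and without it.
"""

from credmeta import (
    Dataset,
    GenotypeCountRecord,
    PipelineConfig,
    run_sensitivity,
)


def rec(study_id, case, control, ethnicity="white"):
    return GenotypeCountRecord(
        variant_id="rs123", gene="DEMO", phenotype="CD", study_id=study_id,
        ethnicity=ethnicity,
        case_wtwt=case[0], case_wtvar=case[1], case_varvar=case[2],
        control_wtwt=control[0], control_wtvar=control[1], control_varvar=control[2],
    )


ds = Dataset(records=[
    rec("s1", (120, 70, 10), (130, 60, 10)),
    rec("s2", (110, 75, 15), (128, 62, 10)),
    rec("s3", (125, 65, 10), (135, 58, 7)),
    rec("s4", (118, 70, 12), (132, 60, 8)),
    # inflated effect + controls with zero heterozygotes (gross HWE violation)
    rec("s_flawed", (60, 100, 40), (160, 0, 40), ethnicity="other"),
])

cfg = PipelineConfig(drop_hwe_violating=True, drop_non_white=True)
reduced, deltas, log = run_sensitivity(ds, cfg)

for entry in log:
    print(f"excluded {entry.study_id}: {entry.reason}")
print()
print(deltas[["model", "delta_log_or", "or_ratio", "significance_flip"]]
      .round(4).to_string(index=False))
print(
    "\nNegative delta_log_or: removing the flawed study pulls the pooled\n"
    "odds ratio back toward the remaining (homogeneous) studies - here the\n"
    "apparent association was carried by that one study, so significance\n"
    "flips. A robust association shows small deltas and no flips."
)
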