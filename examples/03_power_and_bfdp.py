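"""Power and BFDP for one variant, from summary inputs only.

Uses IL23R rs11209026 in paediatric CD: control reference-allele
frequency 0.923, pooled 1158 cases / 4766 controls, published pooled ORs
0.32 (dominant) and 0.97 (recessive). Everything below needs only numbers
a summary table prints.
"""

from credmeta import PowerSpec, bfdp_from_or_ci, exposure_prevalence, power_two_proportions

f_ref, n_cases, n_controls = 0.923, 1158, 4766

for model, or_alt in (("dominant", 0.32), ("recessive", 0.97)):
    p0 = exposure_prevalence(f_ref, model)
    power = power_two_proportions(
        PowerSpec(n_cases=n_cases, n_controls=n_controls, p0=p0, or_alt=or_alt)
    )
    print(f"{model:9s}  exposure prevalence p0 = {p0:.4f}  "
          f"power at OR {or_alt} = {power:.2f}")

print()
for label, or_, ci in (
    ("NOD2 rs2066845 recessive", 8.64, (2.80, 26.69)),
    ("TNF-a rs1800629 additive-2", 4.75, (2.43, 9.26)),
    ("IL23R rs11209026 recessive", 0.97, (0.31, 3.04)),
):
    res = bfdp_from_or_ci(or_, ci)
    mark = "noteworthy" if res.noteworthy else "not noteworthy"
    print(f"{label:27s} OR {or_:5.2f} CI {ci} -> BFDP {res.bfdp:.3f} ({mark})")

print(
    "\nThe dominant contrast is fully powered (1.00) while the recessive one\n"
    "sits at the alpha floor (0.05): the protective allele is too rare for\n"
    "homozygote comparisons. BFDP < 0.20 marks an association noteworthy at\n"
    "prior 0.05; a huge OR with a wide CI (rs2066845) can still carry a high\n"
    "false-discovery probability."
)
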