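"""Re-grade the packaged published summary tables for paediatric CD and UC.

The packaged fixtures carry, per variant and genetic model, the pooled OR
with 95% CI, p-value, I-squared, power and small-study flag of a published
paediatric IBD field synopsis. BFDP, Venice grades and credibility tiers
are recomputed from those upstream columns.
"""

from credmeta import load_published_models, score_reported

for phenotype in ("CD", "UC"):
    rows = load_published_models(phenotype)
    scored, verdicts = score_reported(rows)
    counts = verdicts["tier"].value_counts().to_dict()
    print(f"paediatric {phenotype}: {len(verdicts)} variants -> {counts}")
    highly = verdicts[verdicts.tier == "highly_credible"]
    if len(highly):
        print("  highly credible:", ", ".join(sorted(highly.variant_id)))
    less = verdicts[verdicts.tier == "less_credible"]
    if len(less):
        print("  less credible:  ", ", ".join(sorted(less.variant_id)))
    print()

print(
    "Expected: 9 highly-credible CD variants (NOD2 x3, IL23R x2, IBD5 x2,\n"
    "ATG16L1, TNF-a) with rs11739135 and rs1050152 in the intermediate tier,\n"
    "and no highly-credible UC variant - every significant UC association\n"
    "fails on BFDP or power."
)
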