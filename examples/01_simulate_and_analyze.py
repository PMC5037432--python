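"""Simulate a six-study candidate-gene dataset and run the full pipeline.

Generates genotype counts for a variant with a true dominant-model odds
ratio of 2.0 (control variant-allele frequency 0.3, 500 cases / 1000
controls per study), then pools all four genetic models, grades them and
classifies the variant.
"""

from credmeta import PipelineConfig, SimulationDesign, run_pipeline, simulate_meta_dataset

design = SimulationDesign(k=6, true_or=2.0, model="dominant", f_ref=0.7, seed=42)
ds = simulate_meta_dataset(design)
print(f"simulated {design.k} studies, "
      f"{sum(r.n_cases for r in ds.records)} cases / "
      f"{sum(r.n_controls for r in ds.records)} controls\n")

result = run_pipeline(ds, PipelineConfig())

cols = ["model", "method", "or_", "ci_low", "ci_high", "p", "i2", "power", "bfdp", "venice"]
print(result.models[cols].round(4).to_string(index=False))
print()
print(result.verdicts.to_string(index=False))
print()
print(
    "The dominant-model pooled OR should sit near the true value 2.0 with a\n"
    "95% CI excluding 1; the induced effects under the other contrasts are\n"
    "weaker. The three-letter grade scores power / heterogeneity / bias, and\n"
    "the tier combines significance across models with BFDP, power and I2."
)
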