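# credmeta

Credibility-graded meta-analysis of candidate-gene case-control association
studies, built for field synopses: settings where many small studies report
genotype counts for the same SNPs and the question is not just "is the pooled
odds ratio significant?" but "how believable is the association once power,
heterogeneity, small-study effects and the prior odds of a true finding are
taken into account?". The packaged fixtures come from a published synopsis of
paediatric inflammatory bowel disease (Crohn's disease and ulcerative
colitis), but every component works on any biallelic SNP case-control data.

## What it computes

From per-study genotype counts (wt/wt, wt/var, var/var in cases and
controls), for each of four genetic models — dominant (wt/var & var/var vs
wt/wt), recessive (var/var vs rest), additive-1 (wt/var vs wt/wt) and
additive-2 (var/var vs wt/wt):

- **Per-study odds ratios.** Woolf estimator on the 2×2 exposure table,
  se = √(1/a + 1/b + 1/c + 1/d), Haldane–Anscombe +0.5 correction on zero
  cells; uninformative tables are dropped with a logged reason.
- **Pooling.** Inverse-variance fixed effect, or DerSimonian–Laird random
  effects with τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)), chosen by Cochran's
  Q test at α = 0.05. Heterogeneity is reported as I² = max(0, (Q − df)/Q)·100
  with a test-based ln H confidence interval.
- **Small-study effects.** Egger regression of θᵢ/seᵢ on 1/seᵢ, two-sided
  t-test of the intercept on k − 2 df (detection threshold p < 0.10).
- **Quality.** Hardy–Weinberg equilibrium in controls per study (1-df
  chi-square, or the exact conditional test when expected counts fall below
  5), and power of the two-sided two-proportion z-test at the pooled OR, with
  control exposure prevalence derived from the reference-allele frequency
  under HWE.
- **Credibility.** Wakefield's Bayesian false-discovery probability from the
  pooled OR and CI alone: with θ = ln OR, V from the CI width and a N(0, W)
  prior effect (defaults π = 0.05, W = (ln 3 / z₀.₉₇₅)²),
  ABF = √((V+W)/V)·exp(−θ²W / (2V(V+W))) and
  BFDP = ABF·PO / (1 + ABF·PO), PO = (1−π)/π. Venice criteria give a
  three-letter A/B/C grade (power / I² / bias), and each variant is
  classified **highly credible** (significant in ≥ 2 models and some model
  has p < 0.05, BFDP < 0.20, power ≥ 0.80 and I² ≤ 50), **less credible**
  (significant in ≥ 2 models, no such model) or **not credible**.
- **Sensitivity.** Re-run after excluding HWE-violating and/or non-white
  studies, with per-model deltas and flip flags.
- **Synthetic data.** A generator for multi-study genotype datasets with
  configurable true OR, genetic model, between-study heterogeneity τ,
  small-study bias and an inbreeding-style HWE distortion F — every stage is
  testable without external data.

## Worked example

`examples/03_power_and_bfdp.py` reproduces published credibility columns for
IL23R rs11209026 (1158 cases / 4766 controls, control reference-allele
frequency 0.923) and three BFDP rows from their printed OR/CI inputs:

```
dominant   exposure prevalence p0 = 0.1481  power at OR 0.32 = 1.00
recessive  exposure prevalence p0 = 0.0059  power at OR 0.97 = 0.05

NOD2 rs2066845 recessive    OR  8.64 CI (2.8, 26.69) -> BFDP 0.464 (not noteworthy)
TNF-a rs1800629 additive-2  OR  4.75 CI (2.43, 9.26) -> BFDP 0.018 (noteworthy)
IL23R rs11209026 recessive  OR  0.97 CI (0.31, 3.04) -> BFDP 0.963 (not noteworthy)
```

The dominant contrast is fully powered while the recessive one sits at the
α floor — the protective allele is too rare for homozygote comparisons — and
a large OR with a wide CI (rs2066845) can still carry a high
false-discovery probability. `examples/02_score_published_summaries.py`
re-grades the full packaged CD/UC tables (9 highly-credible CD variants, 2
less-credible, none for UC); `examples/01_simulate_and_analyze.py` and
`examples/04_sensitivity_reanalysis.py` show the raw-counts pipeline and the
sensitivity machinery.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the packaged summary fixtures through the package's own
code paths, the credibility classification of the paediatric CD tables, three
BFDP values from their printed OR/CI inputs, and the two power endpoints
above, writing one JSON entry per quantity.

See `docs/methods.md` for the statistical model, defaults, boundary
conventions and known limitations.
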