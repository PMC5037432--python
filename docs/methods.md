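# Methods

## Scope and data model

The unit of analysis is a (variant, phenotype) pair with genotype counts
from k independent case-control studies. Counts are wt/wt, wt/var, var/var
per arm, where "wt" denotes the reference allele; "carrier-only" studies
report only carriers vs non-carriers and are analysable under the dominant
model alone. A meta-analysis is run only when at least `min_studies`
(default 3) independent studies contribute analysable data; that rule is
applied per genetic model, since carrier-only records and degenerate tables
can reduce the per-model study count below the variant-level count.

## Per-study effects and pooling

Each study's log odds ratio uses the Woolf estimator with
se = sqrt(1/a + 1/b + 1/c + 1/d). Zero-cell handling is Haldane–Anscombe:
if any cell is zero, 0.5 is added to all four cells (flagged per study).
Tables with an empty case or control margin, or a zero exposure column in
both arms, carry no information about the OR and are dropped from that
model with a logged reason.

Fixed-effect pooling is inverse-variance (not Mantel–Haenszel): it pairs
naturally with the DerSimonian–Laird estimator and differs negligibly at
the study sizes this kind of synopsis handles. Random effects use the
DL moment estimator, tau^2 = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)) computed
with fixed-effect weights, then re-weighting by 1/(se_i² + tau²). The model
switch is the classical rule: fixed effect unless the Q test is significant
at `alpha_het` = 0.05 (strict inequality: Q_p exactly 0.05 keeps the fixed
model). All pooled p-values are two-sided normal z-tests on the pooled log
OR.

I² = max(0, (Q − df)/Q)·100. Its 95% CI uses the test-based ln H method
(H = sqrt(Q/df); se(ln H) from the Q-based formula when Q > k, the moment
approximation when k > 2, degenerate (0, 100) for k = 2 with small Q),
truncated to [0, 100].

The Egger test regresses the standardised effect θᵢ/seᵢ on precision 1/seᵢ
by OLS and tests the intercept two-sided on k − 2 df; detection defaults to
p < 0.10, the conventional cut-off for this low-powered test. It needs
k ≥ 3; below that — or when all precisions coincide and the line is
unidentifiable — the result is "not evaluable" and is treated downstream as
"no small-study effect detected" with a warning in the run log.

## Hardy–Weinberg testing

Controls are tested per study. When all HWE-expected genotype counts are
≥ 5 a 1-df chi-square goodness-of-fit test is used; otherwise the exact
conditional test: conditional on allele counts, P(h heterozygotes) ∝
n!/(n_a! h! n_b!)·2^h, and the p-value sums configurations no more probable
than the observed one. The exact routine is validated in the test suite
against an exact rational-arithmetic enumeration (all tables with n ≤ 12,
plus random tables to n = 30). Note that the two-sided exact p and the
chi-square tail genuinely differ in the mid-p range (differences > 0.1 at
n = 400 are normal); they agree closely in the rejection tail, which is
what the violated/not-violated call uses. Carrier-only records are not
evaluable and are never excluded on HWE grounds.

## Power

Power is the two-sided two-proportion z-test normal approximation with
unequal group sizes and no continuity correction:
p1 = OR·p0/(1 − p0 + OR·p0), delta = (p1 − p0)/se with
se² = p1(1−p1)/n_cases + p0(1−p0)/n_controls, and
power = Φ(−z + delta) + Φ(−z − delta), which equals alpha exactly at
OR = 1. The alternative OR is the pooled meta-analytic estimate; p0 is
derived from the control reference-allele frequency f under HWE per model
(dominant 1 − f², recessive q², additive-1 2fq/(f² + 2fq), additive-2
q²/(f² + q²), q = 1 − f). The uncorrected form was chosen because the
original power software's settings are rarely reported and this variant is
fully specified and reproduces published boundary values (1.00 and 0.05);
mid-range published powers may deviate by a few hundredths under a
continuity-corrected formula.

## BFDP

theta = ln OR and V = ((ln hi − ln lo)/(2 z₀.₉₇₅))² are recovered from the
pooled OR and CI — always available, and near-identical to recovering V
from the p-value. The prior probability of association defaults to
π = 0.05. The prior variance W of the log OR under the alternative defaults
to (ln 3 / z₀.₉₇₅)², i.e. 97.5% prior mass below OR 3; this value was
identified because it reproduces three independent published BFDP columns
(0.465, 0.017, 0.963) from their printed OR/CI inputs, and it is
configurable. The noteworthiness threshold is 0.20 (false discovery costed
at four times a false non-discovery).

## Venice grading and classification

Grades: amount of evidence by power (A ≥ 0.80, B 0.50–0.79, C < 0.50),
replication by I² (A ≤ 25, B 25–49, C ≥ 50), bias by the small-study flag
(B none detected, C detected; A is never assigned because freedom from
bias cannot be positively established from summary data). Boundary
conventions are fixed: power exactly 0.80 → A, I² exactly 25 → A, I²
exactly 50 → C.

Classification: a variant is highly credible when significant (p < 0.05,
strict) in at least two eligible models and at least one significant model
simultaneously has BFDP < 0.20, power ≥ 0.80 and I² ≤ 50 — the criteria are
satisfied existentially by a single "qualifying" model, not conjunctively
across models, which is the only reading that reproduces the published
census. Less credible means significant in ≥ 2 models with no qualifying
model; everything else is not credible. The classifier's heterogeneity
bound is inclusive (I² ≤ 50) while the grade boundary is exclusive: grades
are recomputed from rounded integer I² columns in which an underlying 49.x
prints as 50, and the inclusive bound is the convention that reproduces the
published nine-variant highly-credible set; one published row (I² printed
exactly 50, graded B there) therefore re-grades as C here. Both thresholds
are configurable.

## Synthetic data

The generator states a world, not a dial: defaults are k = 6 studies of
500 cases / 1000 controls, control variant-allele frequency 0.3
(f_ref = 0.7), dominant-model OR 2.0, tau = 0, no small-study bias, no HWE
distortion — a typical well-behaved candidate-gene meta-analysis. Controls
are multinomial from HWE proportions; the fixation parameter F rescales the
heterozygote frequency by (1 − F) and moves the deficit to both homozygotes
(the inbreeding model), emulating genotyping error or stratification.
Study-level effects are ln(true OR) + N(0, tau²) + bias·se_i, imposed on
the designated model's exposure dichotomy; case genotype classes on the
same side of the dichotomy are split at their conditional control
frequencies, and for the additive (genotype-restricted) models the excluded
class keeps its control frequency among cases. What a green simulation test
establishes: calibration of the pooling, heterogeneity, Egger and HWE
machinery under the stated generative model. What it does not: robustness
to covariate confounding, population stratification, linkage
disequilibrium between variants, genotyping error beyond the F distortion,
or shared controls across studies.

## Numerical and design choices

- Continuity constant 0.5, applied to all four cells only when some cell
  is zero.
- Exact-HWE tie handling adds 1e-12 to the observed log-probability before
  the ≤ comparison to absorb floating-point ties between symmetric
  configurations.
- Classification is invariant to model ordering; the qualifying model is
  reported in canonical order (dominant, recessive, additive-1,
  additive-2).
- Ethnicity-based exclusion uses a configurable case-insensitive allow-list
  (default white/european/caucasian), since source tables carry only coarse
  labels.
- Phenotypes (CD, UC, IBD) are fully independent in the data model; the
  possibility of shared controls between phenotype analyses is not modelled.
- Entry points: `run_pipeline` consumes raw counts; `score_reported`
  consumes already-pooled per-model rows and recomputes only the
  downstream credibility columns (BFDP from OR/CI — printed BFDP columns
  are never consulted — plus grades and tiers). The packaged fixture
  tables drive the latter.

## Known limitations

- No Peto OR, Hartung–Knapp adjustment, trim-and-fill, leave-one-out or
  cumulative meta-analysis.
- Power at mid-range values is formula-dependent (see above); only the
  saturated and null endpoints are treated as reproduction targets.
- The rule-driven classifier can disagree with a published prose count
  when the published tables themselves do (it reports five UC variants
  significant in ≥ 2 models where the prose says four); such rows are
  reported as computed, not special-cased.
- Allele-level (per-chromosome) contrasts are deliberately not implemented;
  the four genotype models above are the analysis surface.
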