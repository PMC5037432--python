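"""Quality layer: Hardy-Weinberg testing in controls and statistical power.

HWE in controls is checked per study with a 1-df chi-square goodness-of-fit
test when all HWE-expected genotype counts are at least five, and with the
exact conditional test otherwise (sum, over heterozygote counts compatible
with the observed allele counts, of configurations no more probable than
the observed one). Power uses the classical two-proportion normal
approximation with unequal group sizes and no continuity correction; the
control exposure prevalence is derived from the control reference-allele
frequency under HWE for each genetic model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats
from scipy.special import gammaln

from .contrasts import MODELS

__all__ = [
    "HWEResult",
    "PowerSpec",
    "hwe_test",
    "hwe_exact_p",
    "exposure_prevalence",
    "power_two_proportions",
]

_EXPECTED_MIN = 5.0  # chi-square vs exact dispatch threshold


@dataclass(frozen=True)
class HWEResult:
    method: str  # "chi_square" | "exact"
    p_value: float
    violated: bool
    statistic: float = float("nan")

    @staticmethod
    def not_evaluable() -> "HWEResult":
        return HWEResult(method="not_evaluable", p_value=float("nan"), violated=False)

    @property
    def evaluable(self) -> bool:
        return self.method != "not_evaluable"


def hwe_exact_p(n_wtwt: int, n_wtvar: int, n_varvar: int) -> float:
    """Exact conditional HWE p-value.

    Conditional on the observed allele counts, the probability of ``h``
    heterozygotes among ``n`` diploids is

        P(h) = n! / (n_a! h! n_b!) * 2^h * nA! nB! / (2n)!

    where n_a, n_b are the homozygote counts implied by ``h``. The p-value
    sums P(h') over all heterozygote counts of matching parity whose
    probability does not exceed the observed one.
    """
    n = n_wtwt + n_wtvar + n_varvar
    if n == 0:
        raise ValueError("empty genotype table")
    # orient on the rarer allele for numerical convention (p-value is symmetric)
    n_var = 2 * n_varvar + n_wtvar
    n_wt = 2 * n_wtwt + n_wtvar
    rare = min(n_var, n_wt)

    def log_prob(h: int) -> float:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            gammaln(n + 1)
            - gammaln(hom_rare + 1)
            - gammaln(h + 1)
            - gammaln(hom_common + 1)
            + h * math.log(2.0)
            + gammaln(n_var + 1)
            + gammaln(n_wt + 1)
            - gammaln(2 * n + 1)
        )

    h_obs = n_wtvar
    candidates = range(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    lp = {h: log_prob(h) for h in candidates}
    lp_obs = lp[h_obs]
    # tolerance absorbs floating-point ties between equal-probability configs
    return min(1.0, sum(math.exp(v) for v in lp.values() if v <= lp_obs + 1e-12))


def hwe_test(control_counts: tuple[int, int, int], alpha: float = 0.05) -> HWEResult:
    """Test the control genotype distribution for Hardy-Weinberg equilibrium.

    ``control_counts`` is (wt/wt, wt/var, var/var). Chi-square (1 df) when
    all HWE-expected counts are >= 5, exact conditional test otherwise.
    Carrier-only data (merged genotype classes, passed as ``None``) are not
    evaluable.
    """
    if control_counts is None or any(c is None for c in control_counts):
        return HWEResult.not_evaluable()
    n_wtwt, n_wtvar, n_varvar = (int(c) for c in control_counts)
    if min(n_wtwt, n_wtvar, n_varvar) < 0:
        raise ValueError("negative genotype count")
    n = n_wtwt + n_wtvar + n_varvar
    if n == 0:
        raise ValueError("empty genotype table")
    p_wt = (2 * n_wtwt + n_wtvar) / (2 * n)
    q = 1.0 - p_wt
    expected = (n * p_wt**2, 2 * n * p_wt * q, n * q**2)
    if min(expected) >= _EXPECTED_MIN:
        chi2 = sum(
            (o - e) ** 2 / e
            for o, e in zip((n_wtwt, n_wtvar, n_varvar), expected)
        )
        p = float(stats.chi2.sf(chi2, df=1))
        return HWEResult(method="chi_square", p_value=p, violated=p < alpha, statistic=chi2)
    p = hwe_exact_p(n_wtwt, n_wtvar, n_varvar)
    return HWEResult(method="exact", p_value=p, violated=p < alpha)


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the two-proportion power calculation.

    ``p0`` is the exposure prevalence among controls for the genetic model
    in question (derived from the control reference-allele frequency under
    HWE); ``or_alt`` the alternative odds ratio, typically the pooled
    meta-analytic estimate.
    """

    n_cases: int
    n_controls: int
    p0: float
    or_alt: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must be in (0,1)")
        if not self.or_alt > 0:
            raise ValueError("or_alt must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if min(self.n_cases, self.n_controls) < 1:
            raise ValueError("group sizes must be >= 1")


def exposure_prevalence(f_ref: float, model: str) -> float:
    """Control exposure prevalence implied by HWE for a genetic model.

    With reference-allele frequency ``f`` and variant-allele frequency
    q = 1 - f, genotype frequencies are f^2, 2fq, q^2; the exposed
    proportion within each model's analysed population is

        dominant:   1 - f^2                      (any variant allele)
        recessive:  q^2                          (variant homozygote)
        additive-1: 2fq / (f^2 + 2fq)            (het vs wt/wt only)
        additive-2: q^2 / (f^2 + q^2)            (var/var vs wt/wt only)
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if not 0 < f_ref < 1:
        raise ValueError("f_ref must be strictly inside (0,1)")
    q = 1.0 - f_ref
    if model == "dominant":
        return 1.0 - f_ref**2
    if model == "recessive":
        return q**2
    if model == "additive1":
        return 2 * f_ref * q / (f_ref**2 + 2 * f_ref * q)
    return q**2 / (f_ref**2 + q**2)


def power_two_proportions(spec: PowerSpec) -> float:
    """Power of the two-sided two-proportion z-test (normal approximation).

    The case exposure prevalence under the alternative is
    p1 = OR p0 / (1 - p0 + OR p0). With delta = (p1 - p0)/se, where
    se^2 = p1(1-p1)/n_cases + p0(1-p0)/n_controls, the two-sided power is

        Phi(-z_{1-alpha/2} + delta) + Phi(-z_{1-alpha/2} - delta),

    which reduces to exactly alpha at OR = 1. No continuity correction.
    """
    p0 = spec.p0
    p1 = spec.or_alt * p0 / (1.0 - p0 + spec.or_alt * p0)
    if not 0 < p1 < 1:
        raise ValueError("alternative proportion outside (0,1)")
    se = math.sqrt(p1 * (1 - p1) / spec.n_cases + p0 * (1 - p0) / spec.n_controls)
    z = float(stats.norm.ppf(1.0 - spec.alpha / 2.0))
    delta = (p1 - p0) / se
    return float(stats.norm.cdf(-z + delta) + stats.norm.cdf(-z - delta))
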