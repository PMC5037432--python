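"""Credibility layer: BFDP, Venice grading and the three-tier classification.

The Bayesian false-discovery probability (BFDP) is the posterior
probability of no association given the pooled log odds ratio. With
theta = ln(OR), V the squared standard error recovered from the 95% CI,
and a N(0, W) prior on theta under the alternative, the approximate Bayes
factor (null vs alternative) is

    ABF = sqrt((V + W)/V) * exp(-theta^2 W / (2 V (V + W)))

and BFDP = ABF*PO / (1 + ABF*PO) with prior odds of no association
PO = (1 - pi)/pi. Defaults: pi = 0.05 and W = (ln 3 / z_0.975)^2, i.e. a
prior whose 97.5% point sits at OR 3 — the value that reproduces the
published BFDP columns from their printed OR/CI inputs; both are
configurable.

Venice grading scores three criteria A/B/C: amount of evidence by
statistical power (A >= 0.80, B 0.50-0.79, C < 0.50), replication by
heterogeneity (A I^2 <= 25, B 25-49, C >= 50) and protection from bias by
the small-study test (B when none detected, C otherwise; A is never
assigned because bias can never be positively excluded from summary data).

An association is "highly credible" when it is significant (p < 0.05) in
at least two eligible genetic models and at least one significant model
simultaneously shows BFDP < 0.20, power >= 0.80 and I^2 <= 50 (the
qualifying model); "less credible" when significant in >= 2 models but no
model qualifies; "not credible" otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from scipy import stats

from .contrasts import MODELS
from .meta import EggerResult

__all__ = [
    "BFDPParams",
    "BFDPResult",
    "VeniceGrade",
    "CredibilityVerdict",
    "ModelEvidence",
    "bfdp_from_or_ci",
    "venice_grade",
    "classify_variant",
]

_Z975 = float(stats.norm.ppf(0.975))

#: Prior variance with 97.5% prior mass below OR 3 on the log scale.
DEFAULT_PRIOR_W = (math.log(3.0) / _Z975) ** 2


@dataclass(frozen=True)
class BFDPParams:
    prior_pi: float = 0.05
    prior_W: float = DEFAULT_PRIOR_W
    noteworthy_threshold: float = 0.20

    def __post_init__(self) -> None:
        if not 0 < self.prior_pi < 1:
            raise ValueError("prior_pi must be in (0,1)")
        if not self.prior_W > 0:
            raise ValueError("prior_W must be positive")

    @property
    def prior_odds_null(self) -> float:
        return (1.0 - self.prior_pi) / self.prior_pi


@dataclass(frozen=True)
class BFDPResult:
    theta: float
    V: float
    ABF: float
    PO: float
    bfdp: float
    noteworthy: bool


@dataclass(frozen=True)
class VeniceGrade:
    amount: str
    replication: str
    bias: str

    @property
    def as_string(self) -> str:
        return self.amount + self.replication + self.bias


@dataclass(frozen=True)
class ModelEvidence:
    """The per-model quantities the classifier consumes."""

    p: float
    bfdp: float
    power: float
    i2: float


@dataclass(frozen=True)
class CredibilityVerdict:
    tier: str  # "highly_credible" | "less_credible" | "not_credible"
    n_significant_models: int
    qualifying_model: Optional[str]
    rationale: dict[str, dict[str, bool]] = field(default_factory=dict)
    flags: tuple[str, ...] = ()


def bfdp_from_or_ci(
    or_: float,
    ci95: tuple[float, float],
    params: BFDPParams = BFDPParams(),
) -> BFDPResult:
    """BFDP from a pooled OR and its 95% confidence interval.

    The sampling variance is recovered from the CI width on the log scale,
    V = ((ln hi - ln lo) / (2 z_0.975))^2, so the computation needs only
    the two numbers every summary table prints.
    """
    low, high = ci95
    if not (or_ > 0 and 0 < low < high):
        raise ValueError("OR and CI bounds must be positive with low < high")
    theta = math.log(or_)
    V = ((math.log(high) - math.log(low)) / (2.0 * _Z975)) ** 2
    W = params.prior_W
    abf = math.sqrt((V + W) / V) * math.exp(-(theta**2) * W / (2.0 * V * (V + W)))
    po = params.prior_odds_null
    bfdp = abf * po / (1.0 + abf * po)
    return BFDPResult(
        theta=theta,
        V=V,
        ABF=abf,
        PO=po,
        bfdp=bfdp,
        noteworthy=bfdp < params.noteworthy_threshold,
    )


def venice_grade(power: float, i2: float, egger: "EggerResult | bool | None") -> VeniceGrade:
    """Three-letter Venice grade from power, I^2 and the small-study flag.

    Boundary conventions: power exactly 0.80 grades A; I^2 exactly 25
    grades A; I^2 exactly 50 grades C. ``egger`` may be an
    :class:`~credmeta.meta.EggerResult`, a plain detected/not-detected
    boolean, or ``None`` (not evaluable, treated as not detected).
    """
    if not 0 <= power <= 1:
        raise ValueError("power must be in [0,1]")
    if not 0 <= i2 <= 100:
        raise ValueError("I2 must be in [0,100]")
    amount = "A" if power >= 0.80 else ("B" if power >= 0.50 else "C")
    replication = "A" if i2 <= 25 else ("B" if i2 < 50 else "C")
    detected = egger.detected if isinstance(egger, EggerResult) else bool(egger)
    bias = "C" if detected else "B"
    return VeniceGrade(amount=amount, replication=replication, bias=bias)


def classify_variant(
    per_model_results: Mapping[str, "ModelEvidence | tuple[float, float, float, float]"],
    eligible_models: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    bfdp_max: float = 0.20,
    power_min: float = 0.80,
    i2_max: float = 50.0,
) -> CredibilityVerdict:
    """Three-tier credibility classification across genetic models.

    Only models in ``eligible_models`` (default: all provided) contribute.
    Significance is strict (p < alpha; p exactly at alpha does not count).
    The heterogeneity criterion is inclusive at ``i2_max`` because
    published I^2 values are rounded to integer percent. Model iteration
    order never affects the verdict; the qualifying model is the first
    witness in canonical model order.
    """
    if eligible_models is None:
        eligible_models = list(per_model_results)
    evidence: dict[str, ModelEvidence] = {}
    for m in eligible_models:
        if m not in per_model_results:
            continue
        ev = per_model_results[m]
        if not isinstance(ev, ModelEvidence):
            ev = ModelEvidence(*ev)
        evidence[m] = ev
    if not evidence:
        return CredibilityVerdict(
            tier="not_credible",
            n_significant_models=0,
            qualifying_model=None,
            flags=("no eligible models",),
        )

    rationale: dict[str, dict[str, bool]] = {}
    significant: list[str] = []
    witnesses: list[str] = []
    for m in MODELS:
        if m not in evidence:
            continue
        ev = evidence[m]
        crit = {
            "significant": ev.p < alpha,
            "bfdp_noteworthy": ev.bfdp < bfdp_max,
            "power_adequate": ev.power >= power_min,
            "homogeneous": ev.i2 <= i2_max,
        }
        rationale[m] = crit
        if crit["significant"]:
            significant.append(m)
            if crit["bfdp_noteworthy"] and crit["power_adequate"] and crit["homogeneous"]:
                witnesses.append(m)

    if len(significant) >= 2 and witnesses:
        tier = "highly_credible"
        qualifying: Optional[str] = witnesses[0]
    elif len(significant) >= 2:
        tier = "less_credible"
        qualifying = None
    else:
        tier = "not_credible"
        qualifying = None
    return CredibilityVerdict(
        tier=tier,
        n_significant_models=len(significant),
        qualifying_model=qualifying,
        rationale=rationale,
    )
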