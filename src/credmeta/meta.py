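"""Per-study odds ratios and pooled meta-analysis.

The pooled analysis follows the classical two-step inverse-variance
approach on the log odds-ratio scale:

- fixed effect: weights w_i = 1/se_i^2, pooled theta = sum(w_i theta_i)/sum(w_i);
- DerSimonian-Laird random effects: tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))
  with fixed-effect weights, then re-weight with 1/(se_i^2 + tau^2);
- heterogeneity: Cochran's Q against chi-square(k-1) and
  I^2 = max(0, (Q - df)/Q) * 100, with a test-based ln(H) confidence interval;
- model choice: fixed effect unless the Q test is significant at alpha_het;
- small-study effects: Egger regression of the standardised effect
  theta_i/se_i on precision 1/se_i, t-test on the intercept with k-2 df.

Zero cells are handled with the Haldane-Anscombe correction (add 0.5 to
all four cells); tables carrying no information for a contrast (an empty
margin, or a shared zero column across arms) are dropped from that model
with a signal, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .contrasts import INAPPLICABLE, MODELS, FourfoldTable, build_contrast
from .io import Dataset, GenotypeCountRecord

__all__ = [
    "StudyEffect",
    "PooledEffect",
    "EggerResult",
    "Heterogeneity",
    "MetaResult",
    "UninformativeTable",
    "study_log_or",
    "pool_fixed",
    "pool_random_dl",
    "heterogeneity",
    "select_model",
    "egger_test",
    "meta_analyse",
    "forest_data",
    "funnel_data",
]

_Z975 = float(stats.norm.ppf(0.975))


class UninformativeTable(ValueError):
    """The 2x2 table carries no information about the odds ratio."""


@dataclass(frozen=True)
class StudyEffect:
    """One study's log odds ratio and standard error."""

    study_id: str
    log_or: float
    se: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("se must be positive")

    @property
    def or_(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            math.exp(self.log_or - _Z975 * self.se),
            math.exp(self.log_or + _Z975 * self.se),
        )


@dataclass(frozen=True)
class Heterogeneity:
    Q: float
    Q_p: float
    I2: float
    I2_ci95: tuple[float, float]
    k: int
    evaluable: bool = True


@dataclass(frozen=True)
class PooledEffect:
    """Pooled log odds ratio with heterogeneity bookkeeping."""

    k: int
    method: str  # "fixed" | "random"
    log_or: float
    se: float
    Q: float
    Q_p: float
    I2: float
    I2_ci95: tuple[float, float]
    tau2: float = 0.0
    n_cases: int = 0
    n_controls: int = 0

    @property
    def or_(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            math.exp(self.log_or - _Z975 * self.se),
            math.exp(self.log_or + _Z975 * self.se),
        )

    @property
    def p_value(self) -> float:
        """Two-sided normal z-test of the pooled log OR against zero."""
        return 2.0 * float(stats.norm.sf(abs(self.log_or / self.se)))


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    p_value: float
    detected: bool
    k_used: int
    evaluable: bool = True

    @staticmethod
    def not_evaluable(k: int) -> "EggerResult":
        return EggerResult(
            intercept=float("nan"),
            intercept_se=float("nan"),
            p_value=float("nan"),
            detected=False,
            k_used=k,
            evaluable=False,
        )


def study_log_or(t: FourfoldTable, continuity: float = 0.5) -> StudyEffect:
    """Woolf log odds ratio with Haldane-Anscombe zero-cell handling.

    If any cell is zero, ``continuity`` is added to all four cells before
    taking logs; se = sqrt(1/a + 1/b + 1/c + 1/d) on the (possibly
    corrected) cells. Tables with an empty case or control margin, or with
    a zero column shared by both arms, raise :class:`UninformativeTable`
    so the caller can drop the study from that contrast.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if a + b == 0 or c + d == 0:
        raise UninformativeTable("empty case or control margin")
    if (a == 0 and c == 0) or (b == 0 and d == 0):
        raise UninformativeTable("zero exposure column in both arms")
    corrected = t.corrected
    if min(a, b, c, d) == 0:
        a, b, c, d = a + continuity, b + continuity, c + continuity, d + continuity
        corrected = True
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return StudyEffect(study_id="", log_or=log_or, se=se, corrected=corrected)


def _weights(effects: Sequence[StudyEffect]) -> np.ndarray:
    return np.array([1.0 / (e.se**2) for e in effects])


def _q_statistic(effects: Sequence[StudyEffect]) -> float:
    w = _weights(effects)
    th = np.array([e.log_or for e in effects])
    pooled = float(np.sum(w * th) / np.sum(w))
    return float(np.sum(w * (th - pooled) ** 2))


def pool_fixed(effects: Sequence[StudyEffect]) -> PooledEffect:
    """Inverse-variance fixed-effect pooling."""
    if len(effects) == 0:
        raise ValueError("no effects to pool")
    w = _weights(effects)
    th = np.array([e.log_or for e in effects])
    sw = float(np.sum(w))
    pooled = float(np.sum(w * th) / sw)
    se = 1.0 / math.sqrt(sw)
    het = heterogeneity(effects) if len(effects) >= 2 else Heterogeneity(
        0.0, 1.0, 0.0, (0.0, 0.0), k=1, evaluable=False
    )
    return PooledEffect(
        k=len(effects),
        method="fixed",
        log_or=pooled,
        se=se,
        Q=het.Q,
        Q_p=het.Q_p,
        I2=het.I2,
        I2_ci95=het.I2_ci95,
        tau2=0.0,
    )


def pool_random_dl(effects: Sequence[StudyEffect]) -> PooledEffect:
    """DerSimonian-Laird random-effects pooling (tau^2 truncated at zero)."""
    if len(effects) < 2:
        raise ValueError("random-effects pooling needs >= 2 studies")
    w = _weights(effects)
    th = np.array([e.log_or for e in effects])
    k = len(effects)
    Q = _q_statistic(effects)
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (np.array([e.se**2 for e in effects]) + tau2)
    sw = float(np.sum(w_star))
    pooled = float(np.sum(w_star * th) / sw)
    se = 1.0 / math.sqrt(sw)
    het = heterogeneity(effects)
    return PooledEffect(
        k=k,
        method="random",
        log_or=pooled,
        se=se,
        Q=het.Q,
        Q_p=het.Q_p,
        I2=het.I2,
        I2_ci95=het.I2_ci95,
        tau2=tau2,
    )


def _i2_ci_lnH(Q: float, k: int) -> tuple[float, float]:
    """Test-based 95% CI for I^2 via ln H (Higgins-Thompson).

    H = sqrt(Q/(k-1)); se(ln H) uses the Q-based formula when Q > k and a
    moment approximation otherwise; the interval for H maps to I^2 through
    I^2 = (H^2 - 1)/H^2, truncated to [0, 100]. For k = 2 with small Q the
    se is undefined and the interval degenerates to the full range.
    """
    df = k - 1
    H = math.sqrt(max(Q, df) / df) if df > 0 else 1.0
    lnH = math.log(max(H, 1.0))
    if Q > k:
        se = 0.5 * (math.log(Q) - math.log(df)) / (math.sqrt(2 * Q) - math.sqrt(2 * k - 3))
    elif k > 2:
        se = math.sqrt(1.0 / (2 * (k - 2)) * (1.0 - 1.0 / (3 * (k - 2) ** 2)))
    else:
        return (0.0, 100.0)
    lo_H = math.exp(lnH - _Z975 * se)
    hi_H = math.exp(lnH + _Z975 * se)

    def h_to_i2(h: float) -> float:
        return max(0.0, min(100.0, (h * h - 1.0) / (h * h) * 100.0)) if h > 0 else 0.0

    return (h_to_i2(lo_H), h_to_i2(hi_H))


def heterogeneity(effects: Sequence[StudyEffect]) -> Heterogeneity:
    """Cochran's Q, its p-value, and I^2 with a test-based 95% CI."""
    k = len(effects)
    if k < 2:
        return Heterogeneity(0.0, 1.0, 0.0, (0.0, 0.0), k=k, evaluable=False)
    Q = _q_statistic(effects)
    df = k - 1
    Q_p = float(stats.chi2.sf(Q, df))
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return Heterogeneity(Q, Q_p, I2, _i2_ci_lnH(Q, k), k=k)


def select_model(Q_p: float, alpha_het: float = 0.05) -> str:
    """Fixed effect unless heterogeneity is significant (strict Q_p < alpha)."""
    if not 0 < alpha_het < 1:
        raise ValueError("alpha_het must be in (0,1)")
    return "random" if Q_p < alpha_het else "fixed"


def egger_test(effects: Sequence[StudyEffect], alpha: float = 0.10) -> EggerResult:
    """Egger regression for small-study effects.

    OLS of the standardised effect theta_i/se_i on precision 1/se_i; the
    intercept estimates funnel-plot asymmetry and is tested two-sided on
    k-2 degrees of freedom. Needs at least three studies; below that the
    result is flagged not evaluable (treated downstream as "no small-study
    effect detected", with a warning in the run log).
    """
    k = len(effects)
    if k < 3:
        return EggerResult.not_evaluable(k)
    x = np.array([1.0 / e.se for e in effects])
    y = np.array([e.log_or / e.se for e in effects])
    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0:
        # identical precisions: the slope is undefined, intercept meaningless
        return EggerResult.not_evaluable(k)
    slope = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * xbar)
    resid = y - (intercept + slope * x)
    s2 = float(np.sum(resid**2)) / (k - 2)
    se_int = math.sqrt(s2 * (1.0 / k + xbar**2 / sxx))
    if se_int == 0:
        p = 1.0 if intercept == 0 else 0.0
    else:
        p = 2.0 * float(stats.t.sf(abs(intercept / se_int), k - 2))
    return EggerResult(
        intercept=intercept,
        intercept_se=se_int,
        p_value=p,
        detected=p < alpha,
        k_used=k,
    )


@dataclass
class MetaResult:
    """Everything one (variant, phenotype, model) meta-analysis produced."""

    variant_id: str
    phenotype: str
    model: str
    status: str  # "ok" | "insufficient_studies"
    pooled: Optional[PooledEffect] = None
    egger: Optional[EggerResult] = None
    effects: list[StudyEffect] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (study, reason)
    corrected: list[str] = field(default_factory=list)
    n_cases: int = 0
    n_controls: int = 0

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _study_effects(
    records: Sequence[GenotypeCountRecord], model: str, continuity: float = 0.5
) -> tuple[list[StudyEffect], list[tuple[str, str]], int, int]:
    effects: list[StudyEffect] = []
    dropped: list[tuple[str, str]] = []
    n_cases = n_controls = 0
    for rec in records:
        if not rec.analysable:
            dropped.append((rec.study_id, "empty case or control arm"))
            continue
        table = build_contrast(rec, model)
        if table is INAPPLICABLE:
            dropped.append((rec.study_id, "carrier-only record, model inapplicable"))
            continue
        try:
            eff = study_log_or(table, continuity=continuity)
        except UninformativeTable as e:
            dropped.append((rec.study_id, str(e)))
            continue
        effects.append(
            StudyEffect(
                study_id=rec.study_id,
                log_or=eff.log_or,
                se=eff.se,
                corrected=eff.corrected,
            )
        )
        n_cases += int(table.a + table.b)
        n_controls += int(table.c + table.d)
    return effects, dropped, n_cases, n_controls


def meta_analyse(
    ds: Dataset,
    variant_id: str,
    phenotype: str,
    model: str,
    min_studies: int = 3,
    alpha_het: float = 0.05,
    egger_alpha: float = 0.10,
    continuity: float = 0.5,
) -> MetaResult:
    """Full per-model meta-analysis of one variant.

    Drives contrast building, per-study effects, heterogeneity, the
    fixed/random switch, pooling and the Egger test, recording per-study
    drops and continuity corrections along the way. Per-study problems are
    signalled in ``dropped`` without aborting the variant.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    records = ds.records_for(variant_id, phenotype)
    effects, dropped, n_cases, n_controls = _study_effects(records, model, continuity)
    result = MetaResult(
        variant_id=variant_id,
        phenotype=phenotype,
        model=model,
        status="ok",
        effects=effects,
        dropped=dropped,
        corrected=[e.study_id for e in effects if e.corrected],
        n_cases=n_cases,
        n_controls=n_controls,
    )
    if len(effects) < max(min_studies, 2):
        result.status = "insufficient_studies"
        return result
    het = heterogeneity(effects)
    method = select_model(het.Q_p, alpha_het)
    pooled = pool_random_dl(effects) if method == "random" else pool_fixed(effects)
    pooled = PooledEffect(
        k=pooled.k,
        method=pooled.method,
        log_or=pooled.log_or,
        se=pooled.se,
        Q=pooled.Q,
        Q_p=pooled.Q_p,
        I2=pooled.I2,
        I2_ci95=pooled.I2_ci95,
        tau2=pooled.tau2,
        n_cases=n_cases,
        n_controls=n_controls,
    )
    result.pooled = pooled
    result.egger = egger_test(effects, alpha=egger_alpha)
    return result


def forest_data(result: MetaResult) -> "np.recarray | object":
    """Forest-plot data: per-study label, OR, 95% CI and relative weight."""
    import pandas as pd

    w = _weights(result.effects)
    rel = w / w.sum() if len(w) else w
    rows = [
        {
            "study_id": e.study_id,
            "or": e.or_,
            "ci_low": e.ci95[0],
            "ci_high": e.ci95[1],
            "weight": float(rw),
        }
        for e, rw in zip(result.effects, rel)
    ]
    return pd.DataFrame(rows)


def funnel_data(result: MetaResult):
    """Funnel-plot data: per-study log OR and standard error."""
    import pandas as pd

    return pd.DataFrame(
        [{"study_id": e.study_id, "log_or": e.log_or, "se": e.se} for e in result.effects]
    )
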