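"""End-to-end field-synopsis runs: configuration, orchestration, reports.

Two entry points cover the two kinds of input a synopsis deals with:

- :func:`run_pipeline` starts from raw per-study genotype counts and runs
  the full chain per eligible (variant, phenotype): four genetic-model
  meta-analyses, per-study HWE in controls, power, BFDP, Venice grades
  and the variant-level credibility tier.
- :func:`score_reported` starts from already-pooled per-model summary
  rows (OR, CI, p, power, I^2, small-study flag) — the only form in which
  published synopsis tables exist — and recomputes the downstream
  credibility columns: BFDP, Venice grade and tier.

All thresholds live in :class:`PipelineConfig`, which round-trips through
YAML unchanged. Runs are deterministic for fixed config and input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as _io
from .contrasts import MODELS, variant_allele_freq
from .credibility import (
    DEFAULT_PRIOR_W,
    BFDPParams,
    CredibilityVerdict,
    ModelEvidence,
    bfdp_from_or_ci,
    classify_variant,
    venice_grade,
)
from .io import Dataset, eligible_variants, write_summary_table
from .meta import MetaResult, meta_analyse
from .quality import PowerSpec, exposure_prevalence, hwe_test, power_two_proportions
from .sensitivity import ExclusionCriteria, apply_exclusions, sensitivity_compare

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "score_reported", "run_sensitivity"]

logger = logging.getLogger("credmeta")


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds and knobs of a synopsis run."""

    min_studies: int = 3
    alpha: float = 0.05
    alpha_het: float = 0.05
    egger_alpha: float = 0.10
    hwe_alpha: float = 0.05
    prior_pi: float = 0.05
    prior_W: float = DEFAULT_PRIOR_W
    noteworthy_threshold: float = 0.20
    power_min: float = 0.80
    i2_max: float = 50.0
    continuity: float = 0.5
    drop_hwe_violating: bool = False
    drop_non_white: bool = False
    output_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_studies < 1:
            raise ValueError("min_studies must be >= 1")
        for name in ("alpha", "alpha_het", "egger_alpha", "hwe_alpha", "prior_pi",
                     "noteworthy_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")

    @property
    def bfdp_params(self) -> BFDPParams:
        return BFDPParams(
            prior_pi=self.prior_pi,
            prior_W=self.prior_W,
            noteworthy_threshold=self.noteworthy_threshold,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class PipelineResult:
    """Long-form model table, per-variant verdicts, and the run log."""

    models: pd.DataFrame
    verdicts: pd.DataFrame
    meta: dict[tuple[str, str, str], MetaResult] = field(default_factory=dict)
    hwe: Optional[pd.DataFrame] = None
    log: list[str] = field(default_factory=list)


def _control_f_ref(ds: Dataset, variant_id: str, phenotype: str) -> Optional[float]:
    """Reference-allele frequency in controls: metadata, else pooled counts."""
    info = ds.variant_info(variant_id, phenotype)
    if info is not None and info.ref_allele_freq_controls is not None:
        return info.ref_allele_freq_controls
    het = hom = total = 0
    for rec in ds.records_for(variant_id, phenotype):
        if rec.carrier_only or not rec.analysable:
            continue
        het += rec.control_wtvar
        hom += rec.control_varvar
        total += rec.n_controls
    if total == 0:
        return None
    return 1.0 - (het + 2 * hom) / (2 * total)


def run_pipeline(ds: Dataset, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run the full synopsis chain on raw genotype counts.

    For each (variant, phenotype) with data from at least
    ``config.min_studies`` independent studies, pools the four genetic
    models, tests per-study control HWE, estimates power at the pooled OR,
    computes BFDP from the pooled CI, grades the Venice criteria, and
    classifies the variant. Returns everything in memory; when
    ``config.output_dir`` is set, also writes the wide TSV summary, the
    full-precision JSON mirror and forest/funnel data exports.
    """
    runlog: list[str] = []
    pairs = eligible_variants(ds, config.min_studies)
    for vid, phen in ds.unmatched_records():
        runlog.append(f"warning: no variant metadata for ({vid}, {phen})")
    if not pairs:
        runlog.append("warning: no variant reaches the minimum study count; empty summary")

    model_rows: list[dict] = []
    verdict_rows: list[dict] = []
    hwe_rows: list[dict] = []
    meta_store: dict[tuple[str, str, str], MetaResult] = {}

    for variant_id, phenotype in pairs:
        records = ds.records_for(variant_id, phenotype)
        gene = records[0].gene if records else ""
        f_ref = _control_f_ref(ds, variant_id, phenotype)
        for rec in records:
            counts = (
                None
                if rec.carrier_only
                else (rec.control_wtwt, rec.control_wtvar, rec.control_varvar)
            )
            res = hwe_test(counts, alpha=config.hwe_alpha) if counts else hwe_test(None)
            hwe_rows.append(
                {
                    "variant_id": variant_id,
                    "phenotype": phenotype,
                    "study_id": rec.study_id,
                    "method": res.method,
                    "p": res.p_value,
                    "violated": res.violated,
                }
            )

        per_model: dict[str, ModelEvidence] = {}
        eligible_models: list[str] = []
        for model in MODELS:
            mres = meta_analyse(
                ds,
                variant_id,
                phenotype,
                model,
                min_studies=config.min_studies,
                alpha_het=config.alpha_het,
                egger_alpha=config.egger_alpha,
                continuity=config.continuity,
            )
            meta_store[(variant_id, phenotype, model)] = mres
            for study, reason in mres.dropped:
                runlog.append(f"{variant_id}/{phenotype}/{model}: dropped {study}: {reason}")
            for study in mres.corrected:
                runlog.append(f"{variant_id}/{phenotype}/{model}: continuity-corrected {study}")
            row: dict = {
                "gene": gene,
                "variant_id": variant_id,
                "phenotype": phenotype,
                "model": model,
                "n_studies": len(mres.effects),
                "status": mres.status,
            }
            if not mres.ok:
                if any(r.carrier_only for r in records) and model != "dominant":
                    row["status"] = "inapplicable"
                else:
                    runlog.append(
                        f"{variant_id}/{phenotype}/{model}: insufficient studies "
                        f"({len(mres.effects)} analysable)"
                    )
                model_rows.append(row)
                continue
            pooled = mres.pooled
            assert pooled is not None and mres.egger is not None
            ci = pooled.ci95
            power = float("nan")
            if f_ref is not None and 0 < f_ref < 1:
                p0 = exposure_prevalence(f_ref, model)
                if 0 < p0 < 1:
                    power = power_two_proportions(
                        PowerSpec(
                            n_cases=pooled.n_cases,
                            n_controls=pooled.n_controls,
                            p0=p0,
                            or_alt=pooled.or_,
                            alpha=config.alpha,
                        )
                    )
            bf = bfdp_from_or_ci(pooled.or_, ci, config.bfdp_params)
            grade = (
                venice_grade(power, pooled.I2, mres.egger)
                if not math.isnan(power)
                else None
            )
            if not mres.egger.evaluable:
                runlog.append(
                    f"{variant_id}/{phenotype}/{model}: Egger not evaluable "
                    f"(k={mres.egger.k_used}); treated as no small-study effect"
                )
            row.update(
                {
                    "method": pooled.method,
                    "or_": pooled.or_,
                    "log_or": pooled.log_or,
                    "se": pooled.se,
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                    "p": pooled.p_value,
                    "Q": pooled.Q,
                    "Q_p": pooled.Q_p,
                    "i2": pooled.I2,
                    "i2_lo": pooled.I2_ci95[0],
                    "i2_hi": pooled.I2_ci95[1],
                    "tau2": pooled.tau2,
                    "n_cases": pooled.n_cases,
                    "n_controls": pooled.n_controls,
                    "power": power,
                    "bfdp": bf.bfdp,
                    "egger_p": mres.egger.p_value,
                    "egger_detected": mres.egger.detected,
                    "venice": grade.as_string if grade else "n/a",
                }
            )
            model_rows.append(row)
            if not math.isnan(power):
                eligible_models.append(model)
                per_model[model] = ModelEvidence(
                    p=pooled.p_value, bfdp=bf.bfdp, power=power, i2=pooled.I2
                )

        verdict = classify_variant(
            per_model,
            eligible_models=eligible_models,
            alpha=config.alpha,
            bfdp_max=config.noteworthy_threshold,
            power_min=config.power_min,
            i2_max=config.i2_max,
        )
        verdict_rows.append(
            {
                "gene": gene,
                "variant_id": variant_id,
                "phenotype": phenotype,
                "tier": verdict.tier,
                "n_significant_models": verdict.n_significant_models,
                "qualifying_model": verdict.qualifying_model,
            }
        )

    models = pd.DataFrame(model_rows)
    verdicts = pd.DataFrame(
        verdict_rows,
        columns=["gene", "variant_id", "phenotype", "tier", "n_significant_models",
                 "qualifying_model"],
    )
    result = PipelineResult(
        models=models,
        verdicts=verdicts,
        meta=meta_store,
        hwe=pd.DataFrame(hwe_rows),
        log=runlog,
    )
    for line in runlog:
        logger.info(line)
    if config.output_dir is not None and not models.empty:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    merged = result.models.merge(
        result.verdicts[["variant_id", "phenotype", "tier"]],
        on=["variant_id", "phenotype"],
        how="left",
    )
    ok = merged[merged["status"] == "ok"]
    if not ok.empty:
        write_summary_table(ok, outdir / "summary.tsv", outdir / "summary.json")
    from .meta import forest_data, funnel_data

    for (vid, phen, model), mres in result.meta.items():
        if not mres.ok:
            continue
        stem = f"{vid}_{phen}_{model}"
        forest_data(mres).to_csv(outdir / f"forest_{stem}.tsv", sep="\t", index=False)
        funnel_data(mres).to_csv(outdir / f"funnel_{stem}.tsv", sep="\t", index=False)
    (outdir / "run.log").write_text("\n".join(result.log) + "\n")


def score_reported(
    rows: pd.DataFrame, config: PipelineConfig = PipelineConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Credibility scoring of already-pooled per-model summary rows.

    ``rows`` needs one row per (variant, phenotype, model) with columns
    ``or_``, ``ci_low``, ``ci_high``, ``p``, ``power``, ``i2``,
    ``n_studies`` and ``egger_detected`` (missing power/i2/egger default
    to NaN/False). BFDP is recomputed from OR and CI; the printed BFDP, if
    any, is not consulted. Returns the augmented per-model table and the
    per-variant verdict table.
    """
    required = {"variant_id", "phenotype", "model", "or_", "ci_low", "ci_high", "p"}
    missing = required - set(rows.columns)
    if missing:
        raise KeyError(f"summary rows lack columns: {sorted(missing)}")
    rows = rows.copy()
    if "n_studies" not in rows.columns:
        rows["n_studies"] = config.min_studies
    if "egger_detected" not in rows.columns:
        rows["egger_detected"] = False

    bfdps, grades = [], []
    for r in rows.itertuples(index=False):
        bf = bfdp_from_or_ci(float(r.or_), (float(r.ci_low), float(r.ci_high)),
                             config.bfdp_params)
        bfdps.append(bf.bfdp)
        power = float(getattr(r, "power", float("nan")))
        i2 = float(getattr(r, "i2", float("nan")))
        if math.isnan(power) or math.isnan(i2):
            grades.append("n/a")
        else:
            grades.append(venice_grade(power, i2, bool(r.egger_detected)).as_string)
    rows["bfdp"] = bfdps
    rows["venice"] = grades

    verdict_rows = []
    for (vid, phen), grp in rows.groupby(["variant_id", "phenotype"], sort=False):
        eligible = grp[grp["n_studies"] >= config.min_studies]
        per_model = {
            r.model: ModelEvidence(
                p=float(r.p),
                bfdp=float(r.bfdp),
                power=float(getattr(r, "power", float("nan"))),
                i2=float(getattr(r, "i2", float("nan"))),
            )
            for r in eligible.itertuples(index=False)
        }
        verdict: CredibilityVerdict = classify_variant(
            per_model,
            alpha=config.alpha,
            bfdp_max=config.noteworthy_threshold,
            power_min=config.power_min,
            i2_max=config.i2_max,
        )
        verdict_rows.append(
            {
                "gene": grp["gene"].iloc[0] if "gene" in grp.columns else "",
                "variant_id": vid,
                "phenotype": phen,
                "tier": verdict.tier,
                "n_significant_models": verdict.n_significant_models,
                "qualifying_model": verdict.qualifying_model,
            }
        )
    return rows, pd.DataFrame(verdict_rows)


def run_sensitivity(
    ds: Dataset,
    config: PipelineConfig,
    criteria: Optional[ExclusionCriteria] = None,
) -> tuple[PipelineResult, pd.DataFrame, list]:
    """Primary analysis, reduced analysis after exclusions, and deltas.

    With no active exclusion flag the reduced analysis reproduces the
    primary one bit-for-bit and all deltas are zero.
    """
    if criteria is None:
        criteria = ExclusionCriteria(
            drop_hwe_violating=config.drop_hwe_violating,
            drop_non_white=config.drop_non_white,
            hwe_alpha=config.hwe_alpha,
        )
    primary = run_pipeline(ds, replace(config, output_dir=None))
    reduced_ds = ds
    exclusion_log: list = []
    for variant_id, phenotype in eligible_variants(ds, config.min_studies):
        reduced_ds, log = apply_exclusions(reduced_ds, variant_id, phenotype, criteria)
        exclusion_log.extend(log)
    reduced = run_pipeline(reduced_ds, replace(config, output_dir=None))

    keys = ["variant_id", "phenotype", "model"]
    cols = keys + ["log_or", "p"]
    full_ok = primary.models[primary.models["status"] == "ok"][cols]
    red_ok = reduced.models[reduced.models["status"] == "ok"][cols]
    shared = full_ok.merge(red_ok[keys], on=keys)  # variants may lose model eligibility
    red_shared = red_ok.merge(full_ok[keys], on=keys)
    full_t = full_ok.merge(
        primary.verdicts[["variant_id", "phenotype", "tier"]], on=keys[:2], how="left"
    ).merge(shared[keys], on=keys)
    red_t = red_ok.merge(
        reduced.verdicts[["variant_id", "phenotype", "tier"]], on=keys[:2], how="left"
    ).merge(red_shared[keys], on=keys)
    deltas = sensitivity_compare(full_t, red_t)
    return reduced, deltas, exclusion_log
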