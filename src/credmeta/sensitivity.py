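"""Sensitivity re-analysis: exclude HWE-violating or non-white studies.

The synopsis re-runs its meta-analyses after dropping (a) studies whose
control genotypes violate Hardy-Weinberg equilibrium at alpha 0.05 and
(b) studies conducted in non-white populations, then compares pooled
effects against the primary analysis. Carrier-only records cannot be
HWE-tested (the genotype classes are merged) and are never dropped on
HWE grounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Dataset
from .quality import hwe_test

__all__ = ["ExclusionCriteria", "ExclusionLogEntry", "apply_exclusions", "sensitivity_compare"]

#: Ethnicity labels counted as "white" populations (case-insensitive).
DEFAULT_WHITE_LABELS = frozenset({"white", "european", "caucasian"})


@dataclass(frozen=True)
class ExclusionCriteria:
    drop_hwe_violating: bool = False
    drop_non_white: bool = False
    hwe_alpha: float = 0.05
    white_labels: frozenset[str] = DEFAULT_WHITE_LABELS

    @property
    def trivial(self) -> bool:
        return not (self.drop_hwe_violating or self.drop_non_white)


@dataclass(frozen=True)
class ExclusionLogEntry:
    variant_id: str
    phenotype: str
    study_id: str
    reason: str


def apply_exclusions(
    ds: Dataset,
    variant_id: str,
    phenotype: str,
    crit: ExclusionCriteria,
) -> tuple[Dataset, list[ExclusionLogEntry]]:
    """Filter one variant's records per the exclusion criteria.

    Returns the filtered dataset (records for other variants untouched)
    and a log naming each dropped study and why. Idempotent: re-applying
    the same criteria to the result drops nothing further.
    """
    log: list[ExclusionLogEntry] = []
    keep = []
    for rec in ds.records:
        if rec.variant_id != variant_id or rec.phenotype != phenotype:
            keep.append(rec)
            continue
        reason = None
        if crit.drop_non_white and rec.ethnicity.strip().lower() not in crit.white_labels:
            reason = f"non-white population ({rec.ethnicity or 'unlabelled'})"
        if reason is None and crit.drop_hwe_violating and not rec.carrier_only:
            res = hwe_test(
                (rec.control_wtwt, rec.control_wtvar, rec.control_varvar),
                alpha=crit.hwe_alpha,
            )
            if res.violated:
                reason = f"controls violate HWE (p={res.p_value:.3g}, {res.method})"
        if reason is None:
            keep.append(rec)
        else:
            log.append(ExclusionLogEntry(variant_id, phenotype, rec.study_id, reason))
    return ds.subset(keep), log


def sensitivity_compare(full: pd.DataFrame, reduced: pd.DataFrame) -> pd.DataFrame:
    """Per-model deltas between a primary and a reduced analysis.

    Both inputs are long-form result tables keyed by (variant_id,
    phenotype, model) carrying at least ``log_or`` and ``p`` (and
    optionally ``tier``). Returns one row per key with the log-OR shift,
    the ratio of ORs, and significance / tier flips.
    """
    keys = ["variant_id", "phenotype", "model"]
    for df, name in ((full, "full"), (reduced, "reduced")):
        if not set(keys) <= set(df.columns):
            raise KeyError(f"{name} results lack key columns {keys}")
    merged = full.merge(reduced, on=keys, suffixes=("_full", "_reduced"), how="outer")
    missing = merged[merged["log_or_full"].isna() | merged["log_or_reduced"].isna()]
    if len(missing):
        raise KeyError(
            "result keys do not match: "
            + ", ".join(map(str, missing[keys].itertuples(index=False, name=None)))
        )
    out = merged[keys].copy()
    out["delta_log_or"] = merged["log_or_reduced"] - merged["log_or_full"]
    out["or_ratio"] = np.exp(out["delta_log_or"])
    out["sig_full"] = merged["p_full"] < 0.05
    out["sig_reduced"] = merged["p_reduced"] < 0.05
    out["significance_flip"] = out["sig_full"] != out["sig_reduced"]
    if "tier_full" in merged.columns and "tier_reduced" in merged.columns:
        out["tier_flip"] = merged["tier_full"] != merged["tier_reduced"]
    return out
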