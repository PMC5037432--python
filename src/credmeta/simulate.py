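"""Synthetic multi-study case-control genotype data.

The generator emulates the data structure the meta-analysis pipeline
consumes: ``k`` independent case-control studies genotyping one biallelic
SNP. Controls are drawn multinomially from Hardy-Weinberg genotype
proportions built from the control reference-allele frequency, optionally
distorted by an inbreeding-like fixation coefficient F (heterozygote
frequency scaled by 1 - F, the deficit moved to the homozygotes) to
emulate HWE violation. Each study carries a log odds ratio

    theta_i = ln(true_or) + Normal(0, tau^2) + bias * se_i

imposed on the designated genetic model's exposure dichotomy; the other
three contrasts inherit whatever effect that single causal dichotomy
induces. The ``bias * se_i`` term is the canonical small-study mechanism
the Egger intercept targets (se_i is the anticipated standard error from
the study's size and exposure frequencies). Case genotypes are consistent
with the imposed effect: genotype classes on the same side of the
dichotomy are split in proportion to their conditional control
frequencies.

Everything is driven by a single integer seed and is byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence, Union

import numpy as np

from .contrasts import MODELS
from .io import Dataset, GenotypeCountRecord, VariantInfo

__all__ = ["SimulationDesign", "simulate_study_counts", "simulate_meta_dataset", "write_design_tsv"]


@dataclass(frozen=True)
class SimulationDesign:
    """Generative parameters of a synthetic multi-study dataset.

    Defaults describe a typical candidate-gene meta-analysis in this
    field: six studies of 500 cases / 1000 controls each, a common
    variant (control variant-allele frequency 0.3, i.e. f_ref = 0.7), a
    dominant-model odds ratio of 2.0, and no heterogeneity, small-study
    bias or HWE distortion.
    """

    k: int = 6
    n_cases_per_study: Union[int, Sequence[int]] = 500
    n_controls_per_study: Union[int, Sequence[int]] = 1000
    f_ref: float = 0.7
    model: str = "dominant"
    true_or: float = 2.0
    tau: float = 0.0
    small_study_bias: float = 0.0
    hwe_fixation_F: float = 0.0
    seed: int = 0
    variant_id: str = "rs0000001"
    gene: str = "SIMGENE"
    phenotype: str = "CD"
    ethnicity: str = "white"

    def __post_init__(self) -> None:
        if not 0 < self.f_ref < 1:
            raise ValueError("f_ref must be in (0,1)")
        if not self.true_or > 0:
            raise ValueError("true_or must be positive")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not 0 <= self.hwe_fixation_F < 1:
            raise ValueError("hwe_fixation_F must be in [0,1)")

    def study_sizes(self, study_index: int) -> tuple[int, int]:
        def pick(v) -> int:
            return int(v if isinstance(v, (int, np.integer)) else v[study_index])

        return pick(self.n_cases_per_study), pick(self.n_controls_per_study)

    def control_genotype_probs(self) -> tuple[float, float, float]:
        """(wt/wt, wt/var, var/var) control frequencies, F-distorted."""
        p, q, F = self.f_ref, 1.0 - self.f_ref, self.hwe_fixation_F
        het = 2 * p * q * (1.0 - F)
        probs = (p * p + F * p * q, het, q * q + F * p * q)
        if any(not 0 <= x <= 1 for x in probs):
            raise ValueError("genotype probabilities outside [0,1] after distortion")
        return probs


def _odds_to_prob(p0: float, or_: float) -> float:
    return or_ * p0 / (1.0 - p0 + or_ * p0)


def _anticipated_se(n1: int, n2: int, p1: float, p0: float) -> float:
    """Expected log-OR standard error from expected 2x2 cell counts."""
    cells = (n1 * p1, n1 * (1 - p1), n2 * p0, n2 * (1 - p0))
    return math.sqrt(sum(1.0 / max(c, 0.5) for c in cells))


def simulate_study_counts(
    design: SimulationDesign, study_index: int, rng: np.random.Generator
) -> GenotypeCountRecord:
    """Draw one study's genotype counts under the design.

    The causal dichotomy is the designated model's exposure split; case
    counts are binomial in the exposed class with the study-specific odds
    ratio applied to the control exposure prevalence.
    """
    n_cases, n_controls = design.study_sizes(study_index)
    g_wtwt, g_het, g_hom = design.control_genotype_probs()
    ctrl = rng.multinomial(n_controls, [g_wtwt, g_het, g_hom])

    # study-level log OR: shared effect + heterogeneity + small-study bias
    theta = math.log(design.true_or)
    if design.tau > 0:
        theta += rng.normal(0.0, design.tau)
    model = design.model
    if model == "dominant":
        p0 = g_het + g_hom
    elif model == "recessive":
        p0 = g_hom
    elif model == "additive1":
        p0 = g_het / (g_het + g_wtwt)
    else:
        p0 = g_hom / (g_hom + g_wtwt)
    if design.small_study_bias != 0.0:
        se_hat = _anticipated_se(n_cases, n_controls, _odds_to_prob(p0, design.true_or), p0)
        theta += design.small_study_bias * se_hat
    p1 = _odds_to_prob(p0, math.exp(theta))
    if not 0 < p1 < 1:
        raise ValueError("case exposure probability outside (0,1)")

    if model in ("dominant", "recessive"):
        exposed = int(rng.binomial(n_cases, p1))
        unexposed = n_cases - exposed
        if model == "dominant":
            # split carriers between het and hom at control conditional frequencies
            w = g_het / (g_het + g_hom) if g_het + g_hom > 0 else 0.0
            het = int(rng.binomial(exposed, w))
            counts = (unexposed, het, exposed - het)
        else:
            w = g_wtwt / (g_wtwt + g_het) if g_wtwt + g_het > 0 else 0.0
            wtwt = int(rng.binomial(unexposed, w))
            counts = (wtwt, unexposed - wtwt, exposed)
    else:
        # the excluded genotype class keeps its control frequency among cases
        if model == "additive1":
            hom = int(rng.binomial(n_cases, g_hom))
            rest = n_cases - hom
            het = int(rng.binomial(rest, p1))
            counts = (rest - het, het, hom)
        else:
            het = int(rng.binomial(n_cases, g_het))
            rest = n_cases - het
            hom = int(rng.binomial(rest, p1))
            counts = (rest - hom, het, hom)

    return GenotypeCountRecord(
        variant_id=design.variant_id,
        gene=design.gene,
        phenotype=design.phenotype,
        study_id=f"study_{study_index + 1:02d}",
        ethnicity=design.ethnicity,
        case_wtwt=counts[0],
        case_wtvar=counts[1],
        case_varvar=counts[2],
        control_wtwt=int(ctrl[0]),
        control_wtvar=int(ctrl[1]),
        control_varvar=int(ctrl[2]),
    )


def simulate_meta_dataset(design: SimulationDesign) -> Dataset:
    """Simulate a ``k``-study dataset sharing one variant and phenotype."""
    rng = np.random.default_rng(design.seed)
    records = [simulate_study_counts(design, i, rng) for i in range(design.k)]
    info = VariantInfo(
        variant_id=design.variant_id,
        gene=design.gene,
        phenotype=design.phenotype,
        ref_allele_freq_controls=design.f_ref,
    )
    return Dataset(
        records=records,
        variants=[info],
        provenance=f"simulated(seed={design.seed})",
    )


def write_design_tsv(design: SimulationDesign, path) -> None:
    """Simulate under ``design`` and write a reader-conformant TSV."""
    from .io import write_dataset

    write_dataset(simulate_meta_dataset(design), path)
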