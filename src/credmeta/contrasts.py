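"""Genetic-model contrasts: genotype counts -> 2x2 exposure tables.

Each biallelic SNP is analysed under four genotype re-codings:

- dominant:   wt/var & var/var  vs  wt/wt
- recessive:  var/var           vs  wt/wt & wt/var
- additive-1: wt/var            vs  wt/wt   (var/var individuals excluded)
- additive-2: var/var           vs  wt/wt   (heterozygotes excluded)

The additive contrasts are genotype-restricted two-genotype comparisons:
the third genotype class is dropped, not recoded. Carrier-only records
(variant-allele carriers vs non-carriers) support the dominant model only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import GenotypeCountRecord

__all__ = [
    "MODELS",
    "FourfoldTable",
    "Inapplicable",
    "INAPPLICABLE",
    "build_contrast",
    "variant_allele_freq",
]

MODELS = ("dominant", "recessive", "additive1", "additive2")


class Inapplicable:
    """Sentinel: this genetic model cannot be formed from the record."""

    def __repr__(self) -> str:  # pragma: no cover
        return "INAPPLICABLE"

    def __bool__(self) -> bool:
        return False


INAPPLICABLE = Inapplicable()


@dataclass(frozen=True)
class FourfoldTable:
    """A 2x2 case-control exposure table.

    a = exposed cases, b = unexposed cases, c = exposed controls,
    d = unexposed controls. Cells are reals so a continuity correction
    (same constant added to all four cells) can be applied downstream;
    ``corrected`` records whether it was.
    """

    a: float
    b: float
    c: float
    d: float
    model: str
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def analysable(self) -> bool:
        return self.a + self.b > 0 and self.c + self.d > 0

    @property
    def odds_ratio(self) -> float:
        """Crude cross-product ratio ad/bc (inf/nan on zero margins)."""
        if self.b * self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return (self.a * self.d) / (self.b * self.c)


def build_contrast(rec: GenotypeCountRecord, model: str):
    """Form the 2x2 exposure table for ``model``, or ``INAPPLICABLE``.

    Carrier-only records (merged wt/var & var/var count) are only
    informative about carriage of the variant allele, i.e. the dominant
    dichotomy; every other model returns :data:`INAPPLICABLE`.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if rec.carrier_only:
        if model != "dominant":
            return INAPPLICABLE
        return FourfoldTable(
            a=rec.case_wtvar,
            b=rec.case_wtwt,
            c=rec.control_wtvar,
            d=rec.control_wtwt,
            model=model,
        )
    if model == "dominant":
        a, b = rec.case_wtvar + rec.case_varvar, rec.case_wtwt
        c, d = rec.control_wtvar + rec.control_varvar, rec.control_wtwt
    elif model == "recessive":
        a, b = rec.case_varvar, rec.case_wtwt + rec.case_wtvar
        c, d = rec.control_varvar, rec.control_wtwt + rec.control_wtvar
    elif model == "additive1":
        a, b = rec.case_wtvar, rec.case_wtwt
        c, d = rec.control_wtvar, rec.control_wtwt
    else:  # additive2
        a, b = rec.case_varvar, rec.case_wtwt
        c, d = rec.control_varvar, rec.control_wtwt
    return FourfoldTable(a=a, b=b, c=c, d=d, model=model)


def variant_allele_freq(rec: GenotypeCountRecord, arm: str = "controls") -> float:
    """Variant-allele frequency (wtvar + 2*varvar) / 2N in one arm.

    Undefined for carrier-only records, where heterozygotes and variant
    homozygotes cannot be separated.
    """
    if rec.carrier_only:
        raise ValueError("allele frequency is not defined for carrier-only records")
    if arm == "cases":
        het, hom, n = rec.case_wtvar, rec.case_varvar, rec.n_cases
    elif arm == "controls":
        het, hom, n = rec.control_wtvar, rec.control_varvar, rec.n_controls
    else:
        raise ValueError(f"unknown arm {arm!r}")
    if n == 0:
        raise ValueError(f"no individuals in {arm}")
    return (het + 2 * hom) / (2 * n)
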