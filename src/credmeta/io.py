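"""Tabular data model for multi-study case-control genotype counts.

A study contributes, for one SNP and one phenotype (CD, UC or IBD), the
genotype breakdown of its cases and controls: wt/wt, wt/var and var/var,
where "wt" is the reference allele and "var" the variant allele. Some
studies report only carrier status (wt/var & var/var merged); such records
set ``carrier_only`` and are analysable under the dominant model only.

Input and output are plain TSV/CSV; a machine-readable JSON mirror of the
summary table is written alongside for lossless round-trips.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "GenotypeCountRecord",
    "VariantInfo",
    "Dataset",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
    "eligible_variants",
    "write_summary_table",
    "read_summary_json",
    "load_published_models",
    "load_published_variants",
    "PHENOTYPES",
    "COUNT_COLUMNS",
]

PHENOTYPES = ("CD", "UC", "IBD")

COUNT_COLUMNS = (
    "case_wtwt",
    "case_wtvar",
    "case_varvar",
    "control_wtwt",
    "control_wtvar",
    "control_varvar",
)

#: Mandatory columns of a genotype-count table.
REQUIRED_COLUMNS = ("variant_id", "gene", "phenotype", "study_id") + COUNT_COLUMNS

#: Fixed block order of the per-model summary table.
MODEL_ORDER = ("dominant", "recessive", "additive1", "additive2")


@dataclass(frozen=True)
class GenotypeCountRecord:
    """One study's genotype counts for one variant and phenotype.

    For carrier-only records the merged carrier count (wt/var & var/var)
    is stored in the ``*_wtvar`` slot and ``*_varvar`` is ``None``.
    """

    variant_id: str
    gene: str
    phenotype: str
    study_id: str
    case_wtwt: int
    case_wtvar: int
    control_wtwt: int
    control_wtvar: int
    case_varvar: Optional[int] = None
    control_varvar: Optional[int] = None
    ethnicity: str = ""
    carrier_only: bool = False

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        for name in COUNT_COLUMNS:
            v = getattr(self, name)
            if v is None:
                if not self.carrier_only or not name.endswith("varvar"):
                    raise ValueError(f"{name} missing on non-carrier record")
                continue
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.carrier_only and (
            self.case_varvar is not None or self.control_varvar is not None
        ):
            raise ValueError("carrier_only records must leave var/var counts empty")

    @property
    def n_cases(self) -> int:
        return self.case_wtwt + self.case_wtvar + (self.case_varvar or 0)

    @property
    def n_controls(self) -> int:
        return self.control_wtwt + self.control_wtvar + (self.control_varvar or 0)

    @property
    def analysable(self) -> bool:
        """Degenerate arms (no cases or no controls) are skipped, not errors."""
        return self.n_cases >= 1 and self.n_controls >= 1

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.variant_id, self.phenotype, self.study_id)


@dataclass(frozen=True)
class VariantInfo:
    """Per-variant metadata: gene, phenotype and allele frequencies.

    ``ref_allele_freq_controls`` is the wild-type (reference) allele
    frequency among controls; the variant-allele frequency is its
    complement. It feeds the Hardy-Weinberg derivation of exposure
    prevalence used by the power calculation.
    """

    variant_id: str
    gene: str
    phenotype: str
    ref_allele: str = ""
    ref_allele_freq_controls: Optional[float] = None
    maf: Optional[float] = None

    def __post_init__(self) -> None:
        f = self.ref_allele_freq_controls
        if f is not None and not 0.0 <= f <= 1.0:
            raise ValueError(f"ref_allele_freq_controls out of [0,1]: {f}")


@dataclass
class Dataset:
    """A collection of genotype-count records plus variant metadata."""

    records: list[GenotypeCountRecord] = field(default_factory=list)
    variants: list[VariantInfo] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for rec in self.records:
            if rec.key in seen:
                raise DatasetValidationError(
                    [(None, "study_id", f"duplicate (variant, phenotype, study) triple {rec.key}")]
                )
            seen.add(rec.key)

    def variant_info(self, variant_id: str, phenotype: str) -> Optional[VariantInfo]:
        for v in self.variants:
            if v.variant_id == variant_id and v.phenotype == phenotype:
                return v
        return None

    def records_for(self, variant_id: str, phenotype: str) -> list[GenotypeCountRecord]:
        return [
            r
            for r in self.records
            if r.variant_id == variant_id and r.phenotype == phenotype
        ]

    def unmatched_records(self) -> list[tuple[str, str]]:
        """(variant, phenotype) pairs present in records but missing metadata."""
        have = {(v.variant_id, v.phenotype) for v in self.variants}
        return sorted(
            {
                (r.variant_id, r.phenotype)
                for r in self.records
                if (r.variant_id, r.phenotype) not in have
            }
        )

    def subset(self, keep: Iterable[GenotypeCountRecord]) -> "Dataset":
        keep = list(keep)
        return Dataset(records=keep, variants=list(self.variants), provenance=self.provenance)


class DatasetValidationError(ValueError):
    """Raised when an input table violates the data-model invariants.

    ``errors`` is a list of ``(row, field, message)`` with 1-based data row
    numbers (header excluded), so the offending line is easy to find.
    """

    def __init__(self, errors: Sequence[tuple[Optional[int], str, str]]):
        self.errors = list(errors)
        lines = [
            f"row {row if row is not None else '?'}, field {fld}: {msg}"
            for row, fld, msg in self.errors
        ]
        super().__init__("invalid dataset:\n" + "\n".join(lines))


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")


def _cell_empty(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == ""


def _parse_count(v) -> int:
    x = float(v)
    if not x.is_integer() or x < 0:
        raise ValueError(f"non-negative integer required, got {v!r}")
    return int(x)


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no", ""}:
        return False
    raise ValueError(f"boolean required, got {v!r}")


def read_dataset(
    path: str | Path,
    dialect: str = "tsv",
    variants_path: str | Path | None = None,
    column_map: Optional[dict[str, str]] = None,
    provenance: str = "",
) -> Dataset:
    """Read and validate a genotype-count table (and optional variant table).

    Column names are the snake_case field names of
    :class:`GenotypeCountRecord`; ``column_map`` maps foreign header names
    onto them (``{"their_name": "our_name"}``). Rows violating the type
    invariants abort the read with row-level diagnostics.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetValidationError([(None, c, "missing column") for c in missing])

    records: list[GenotypeCountRecord] = []
    errors: list[tuple[Optional[int], str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        carrier = False
        if "carrier_only" in row:
            try:
                carrier = _parse_bool(row["carrier_only"])
            except ValueError as e:
                errors.append((i, "carrier_only", str(e)))
                continue
        # carrier-format rows may also be recognised by empty var/var cells
        if _cell_empty(row["case_varvar"]) and _cell_empty(row["control_varvar"]):
            carrier = True
        counts: dict[str, Optional[int]] = {}
        bad = False
        for name in COUNT_COLUMNS:
            if carrier and name.endswith("varvar"):
                if not _cell_empty(row[name]):
                    errors.append((i, name, "carrier_only rows must leave var/var empty"))
                    bad = True
                counts[name] = None
                continue
            try:
                counts[name] = _parse_count(row[name])
            except ValueError as e:
                errors.append((i, name, str(e)))
                bad = True
        if bad:
            continue
        try:
            rec = GenotypeCountRecord(
                variant_id=str(row["variant_id"]).strip(),
                gene=str(row["gene"]).strip(),
                phenotype=str(row["phenotype"]).strip(),
                study_id=str(row["study_id"]).strip(),
                ethnicity=str(row.get("ethnicity", "")).strip(),
                carrier_only=carrier,
                **counts,  # type: ignore[arg-type]
            )
        except ValueError as e:
            errors.append((i, "-", str(e)))
            continue
        if rec.key in seen:
            errors.append((i, "study_id", f"duplicate (variant, phenotype, study) triple {rec.key}"))
            continue
        seen.add(rec.key)
        records.append(rec)
    if errors:
        raise DatasetValidationError(errors)

    variants: list[VariantInfo] = []
    if variants_path is not None:
        vdf = pd.read_csv(variants_path, sep=_sep(dialect), dtype=str, keep_default_na=False)
        for i, row in enumerate(vdf.itertuples(index=False), start=1):
            row = row._asdict()
            try:
                variants.append(
                    VariantInfo(
                        variant_id=str(row["variant_id"]).strip(),
                        gene=str(row["gene"]).strip(),
                        phenotype=str(row["phenotype"]).strip(),
                        ref_allele=str(row.get("ref_allele", "")).strip(),
                        ref_allele_freq_controls=(
                            None
                            if _cell_empty(row.get("raf_controls", ""))
                            else float(row["raf_controls"])
                        ),
                        maf=None if _cell_empty(row.get("maf", "")) else float(row["maf"]),
                    )
                )
            except ValueError as e:
                errors.append((i, "-", str(e)))
        if errors:
            raise DatasetValidationError(errors)
    return Dataset(records=records, variants=variants, provenance=provenance or str(path))


def write_dataset(ds: Dataset, path: str | Path, dialect: str = "tsv") -> Path:
    """Write a dataset back to a delimited file readable by :func:`read_dataset`."""
    path = Path(path)
    rows = []
    for r in ds.records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "gene": r.gene,
                "phenotype": r.phenotype,
                "study_id": r.study_id,
                "ethnicity": r.ethnicity,
                "case_wtwt": r.case_wtwt,
                "case_wtvar": r.case_wtvar,
                "case_varvar": "" if r.case_varvar is None else r.case_varvar,
                "control_wtwt": r.control_wtwt,
                "control_wtvar": r.control_wtvar,
                "control_varvar": "" if r.control_varvar is None else r.control_varvar,
                "carrier_only": r.carrier_only,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=_sep(dialect), index=False)
    return path


def eligible_variants(ds: Dataset, min_studies: int = 3) -> list[tuple[str, str]]:
    """(variant, phenotype) pairs with analysable data from >= ``min_studies``
    independent studies, ordered by gene then variant id.

    The default of three independent studies is the synopsis' inclusion
    rule for running a meta-analysis at all.
    """
    if min_studies < 1:
        raise ValueError("min_studies must be >= 1")
    counts: dict[tuple[str, str], set[str]] = {}
    genes: dict[tuple[str, str], str] = {}
    for r in ds.records:
        if not r.analysable:
            continue
        key = (r.variant_id, r.phenotype)
        counts.setdefault(key, set()).add(r.study_id)
        genes.setdefault(key, r.gene)
    keep = [k for k, studies in counts.items() if len(studies) >= min_studies]
    return sorted(keep, key=lambda k: (genes[k], k[0], k[1]))


# ---------------------------------------------------------------------------
# summary-table output

_MODEL_BLOCK_COLUMNS = (
    "n_studies",
    "or_",
    "ci_low",
    "ci_high",
    "p",
    "i2",
    "i2_lo",
    "i2_hi",
    "power",
    "bfdp",
    "venice",
)


def write_summary_table(
    results: pd.DataFrame,
    path: str | Path,
    json_path: str | Path | None = None,
    float_format: str = "{:.4g}",
) -> Path:
    """Write the wide per-variant summary table (one block per genetic model).

    ``results`` is the long-form per-(variant, phenotype, model) table
    produced by the pipeline. The TSV mirrors the published layout — one
    row per variant, model blocks in the fixed order dominant, recessive,
    additive-1, additive-2, missing blocks marked ``n/a`` — while the JSON
    mirror keeps full float precision for lossless round-trips.
    """
    if results.empty:
        raise ValueError("results table is empty")
    path = Path(path)
    id_cols = ["gene", "variant_id", "phenotype"]
    extra = [c for c in ("tier",) if c in results.columns]
    rows = []
    for (gene, vid, phen), grp in results.groupby(id_cols, sort=True):
        row: dict[str, object] = {"gene": gene, "variant_id": vid, "phenotype": phen}
        for c in extra:
            row[c] = grp[c].iloc[0]
        by_model = {m: g.iloc[0] for m, g in grp.groupby("model")}
        for model in MODEL_ORDER:
            for col in _MODEL_BLOCK_COLUMNS:
                out = f"{model}_{col}"
                if model not in by_model or col not in grp.columns:
                    row[out] = "n/a"
                    continue
                v = by_model[model][col]
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    row[out] = "n/a"
                elif isinstance(v, float):
                    row[out] = float_format.format(v)
                else:
                    row[out] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(
                {
                    "columns": list(results.columns),
                    "rows": results.where(results.notna(), None).to_dict(orient="records"),
                },
                indent=1,
                default=str,
            )
        )
    return path


def read_summary_json(json_path: str | Path) -> pd.DataFrame:
    """Read back the machine-readable summary written by :func:`write_summary_table`."""
    payload = json.loads(Path(json_path).read_text())
    df = pd.DataFrame(payload["rows"], columns=payload["columns"])
    return df


# ---------------------------------------------------------------------------
# packaged fixtures: published per-model summaries and the variant list

def _data_path(name: str):
    return resources.files("credmeta.data").joinpath(name)


def load_published_models(phenotype: str = "CD") -> pd.DataFrame:
    """Published per-model meta-analysis summaries for paediatric CD or UC.

    One row per (variant, model) with the pooled OR, 95% CI, p-value,
    I² (%), statistical power, BFDP, three-letter Venice grade and the
    small-study-effect flag, as printed in the source synopsis tables.
    Models absent for carrier-only variants (or with too few studies)
    simply have no row.
    """
    name = {"CD": "pediatric_cd_models.tsv", "UC": "pediatric_uc_models.tsv"}.get(phenotype)
    if name is None:
        raise ValueError(f"no published model table for phenotype {phenotype!r}")
    with resources.as_file(_data_path(name)) as p:
        df = pd.read_csv(p, sep="\t")
    df["egger_detected"] = df["egger_detected"].astype(bool)
    df["carrier_only"] = df["carrier_only"].astype(bool)
    return df


def load_published_variants() -> pd.DataFrame:
    """Published variant list: genes, pooled totals, reference-allele frequencies."""
    with resources.as_file(_data_path("pediatric_ibd_variants.tsv")) as p:
        return pd.read_csv(p, sep="\t")
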