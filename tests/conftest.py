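import numpy as np
import pytest

from credmeta import Dataset, GenotypeCountRecord, VariantInfo


def make_record(
    study_id="s1",
    case=(50, 30, 20),
    control=(70, 20, 10),
    variant_id="rs1",
    gene="GENE1",
    phenotype="CD",
    ethnicity="white",
    carrier_only=False,
):
    if carrier_only:
        return GenotypeCountRecord(
            variant_id=variant_id,
            gene=gene,
            phenotype=phenotype,
            study_id=study_id,
            ethnicity=ethnicity,
            case_wtwt=case[0],
            case_wtvar=case[1],
            control_wtwt=control[0],
            control_wtvar=control[1],
            carrier_only=True,
        )
    return GenotypeCountRecord(
        variant_id=variant_id,
        gene=gene,
        phenotype=phenotype,
        study_id=study_id,
        ethnicity=ethnicity,
        case_wtwt=case[0],
        case_wtvar=case[1],
        case_varvar=case[2],
        control_wtwt=control[0],
        control_wtvar=control[1],
        control_varvar=control[2],
    )


@pytest.fixture
def record():
    return make_record()


@pytest.fixture
def small_dataset():
    """Three-study dataset for one variant, plus metadata."""
    # control genotype counts sit near HWE proportions (f_ref ~ 0.8)
    recs = [
        make_record("s1", (50, 30, 20), (64, 32, 4)),
        make_record("s2", (45, 35, 20), (60, 34, 6)),
        make_record("s3", (55, 28, 17), (66, 30, 4)),
    ]
    info = VariantInfo(variant_id="rs1", gene="GENE1", phenotype="CD",
                       ref_allele_freq_controls=0.8)
    return Dataset(records=recs, variants=[info], provenance="test")


@pytest.fixture
def rng():
    return np.random.default_rng(20160927)


def random_effects(rng, k, seed_offset=0):
    """Random per-study effects for oracle comparisons."""
    from credmeta import StudyEffect

    r = np.random.default_rng(rng.integers(2**31) + seed_offset)
    th = r.normal(0, 0.8, size=k)
    se = r.uniform(0.05, 0.6, size=k)
    return [StudyEffect(study_id=f"s{i}", log_or=float(t), se=float(s))
            for i, (t, s) in enumerate(zip(th, se))]
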