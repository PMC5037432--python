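import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.meta_analysis import combine_effects

from credmeta import (
    Dataset,
    StudyEffect,
    egger_test,
    heterogeneity,
    meta_analyse,
    pool_fixed,
    pool_random_dl,
    select_model,
    study_log_or,
)
from credmeta.contrasts import FourfoldTable
from credmeta.meta import UninformativeTable, forest_data, funnel_data

from conftest import make_record, random_effects


def table(a, b, c, d, model="dominant"):
    return FourfoldTable(a=a, b=b, c=c, d=d, model=model)


class TestStudyLogOR:
    def test_hand_computed_example(self):
        eff = study_log_or(table(20, 80, 10, 90))
        assert eff.log_or == pytest.approx(math.log(2.25), abs=1e-4)  # 0.8109
        assert eff.se == pytest.approx(0.41667, abs=1e-5)
        assert not eff.corrected

    def test_balanced_table_is_null(self):
        assert study_log_or(table(10, 10, 10, 10)).log_or == 0.0

    def test_haldane_anscombe_zero_cell(self):
        eff = study_log_or(table(0, 50, 10, 40))
        assert eff.corrected
        assert eff.or_ == pytest.approx((0.5 * 40.5) / (50.5 * 10.5), rel=1e-12)  # 0.0382

    @pytest.mark.parametrize("cells", [(0, 0, 5, 5), (5, 5, 0, 0), (0, 5, 0, 5), (5, 0, 5, 0)])
    def test_uninformative_tables_signalled(self, cells):
        with pytest.raises(UninformativeTable):
            study_log_or(table(*cells))


class TestFixedPooling:
    def test_two_identical_studies(self):
        e = StudyEffect("s", math.log(2.25), 0.41667)
        pooled = pool_fixed([e, StudyEffect("t", e.log_or, e.se)])
        assert pooled.or_ == pytest.approx(2.25, rel=1e-6)
        assert pooled.se == pytest.approx(0.29463, abs=1e-5)
        assert pooled.Q == pytest.approx(0.0, abs=1e-12)

    def test_single_study_identity(self):
        e = StudyEffect("s", 0.3, 0.1)
        pooled = pool_fixed([e])
        assert (pooled.log_or, pooled.se) == (e.log_or, e.se)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_fixed([])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        th=st.lists(st.floats(-2, 2), min_size=2, max_size=8),
        seed=st.integers(0, 10_000),
    )
    def test_pooled_estimate_is_convex_combination(self, th, seed):
        r = np.random.default_rng(seed)
        eff = [StudyEffect(f"s{i}", t, float(r.uniform(0.05, 1.0))) for i, t in enumerate(th)]
        pooled = pool_fixed(eff)
        assert min(th) - 1e-12 <= pooled.log_or <= max(th) + 1e-12

    def test_order_invariance(self, rng):
        eff = random_effects(rng, 6)
        a, b = pool_fixed(eff), pool_fixed(eff[::-1])
        assert a.log_or == pytest.approx(b.log_or, abs=1e-14)
        assert a.se == pytest.approx(b.se, abs=1e-14)


class TestRandomEffectsDL:
    def test_homogeneous_truncates_to_fixed(self):
        e = StudyEffect("s", 0.5, 0.3)
        eff = [e, StudyEffect("t", 0.5, 0.3), StudyEffect("u", 0.5, 0.3)]
        re_, fe = pool_random_dl(eff), pool_fixed(eff)
        assert re_.tau2 == 0.0
        assert re_.log_or == pytest.approx(fe.log_or)
        assert re_.se == pytest.approx(fe.se)

    def test_heterogeneous_pair_hand_computed(self):
        # theta {0, 1}, se 0.2 -> w 25 each, Q 12.5, tau2 (12.5-1)/25 = 0.46
        eff = [StudyEffect("a", 0.0, 0.2), StudyEffect("b", 1.0, 0.2)]
        re_ = pool_random_dl(eff)
        assert re_.tau2 == pytest.approx(0.46, rel=1e-12)
        assert re_.se > pool_fixed(eff).se
        assert re_.log_or == pytest.approx(0.5, abs=1e-12)

    def test_needs_two_studies(self):
        with pytest.raises(ValueError):
            pool_random_dl([StudyEffect("s", 0.1, 0.1)])

    def test_matches_independent_dl_oracle_on_random_instances(self, rng):
        # statsmodels reports the untruncated moment estimate; below zero the
        # DL estimator truncates and the random-effects fit collapses to fixed
        for i in range(100):
            eff = random_effects(rng, int(rng.integers(2, 9)), seed_offset=i)
            mine = pool_random_dl(eff)
            with np.errstate(invalid="ignore"):
                ref = combine_effects(
                    np.array([e.log_or for e in eff]),
                    np.array([e.se**2 for e in eff]),
                    method_re="dl",
                )
            assert mine.tau2 == pytest.approx(max(0.0, float(ref.tau2)), abs=1e-10)
            if float(ref.tau2) > 0:
                assert mine.log_or == pytest.approx(float(ref.mean_effect_re), abs=1e-10)
                assert mine.se == pytest.approx(float(ref.sd_eff_w_re), abs=1e-10)
            else:
                assert mine.log_or == pytest.approx(float(ref.mean_effect_fe), abs=1e-10)
                assert mine.se == pytest.approx(float(ref.sd_eff_w_fe), abs=1e-10)
            fe = pool_fixed(eff)
            assert fe.log_or == pytest.approx(float(ref.mean_effect_fe), abs=1e-10)
            assert fe.se == pytest.approx(float(ref.sd_eff_w_fe), abs=1e-10)

    def test_random_ci_never_narrower_than_fixed(self, rng):
        for i in range(50):
            eff = random_effects(rng, 5, seed_offset=1000 + i)
            assert pool_random_dl(eff).se >= pool_fixed(eff).se - 1e-15


class TestHeterogeneity:
    def test_identical_studies(self):
        eff = [StudyEffect(f"s{i}", 0.4, 0.25) for i in range(4)]
        het = heterogeneity(eff)
        assert het.Q == pytest.approx(0.0, abs=1e-12)
        assert het.I2 == 0.0
        assert het.I2_ci95[0] == 0.0

    def test_q_at_df_boundary_gives_zero_i2(self):
        # two studies at distance making Q exactly k-1 = 1
        se = 1.0
        eff = [StudyEffect("a", 0.0, se), StudyEffect("b", math.sqrt(2), se)]
        het = heterogeneity(eff)
        assert het.Q == pytest.approx(1.0, rel=1e-12)
        assert het.I2 == pytest.approx(0.0, abs=1e-10)

    def test_i2_formula_oracle_on_random_instances(self, rng):
        for i in range(100):
            eff = random_effects(rng, int(rng.integers(2, 10)), seed_offset=5000 + i)
            het = heterogeneity(eff)
            df = len(eff) - 1
            expected = max(0.0, (het.Q - df) / het.Q) * 100.0 if het.Q > 0 else 0.0
            assert het.I2 == pytest.approx(expected, abs=1e-10)
            lo, hi = het.I2_ci95
            assert 0.0 <= lo <= hi <= 100.0


@pytest.mark.parametrize(
    "q_p,expected", [(0.20, "fixed"), (0.01, "random"), (0.05, "fixed")]
)
def test_select_model_threshold(q_p, expected):
    assert select_model(q_p) == expected


class TestEgger:
    def test_identical_studies_not_detected(self):
        # identical precisions: regression degenerate, flagged not evaluable
        eff = [StudyEffect(f"s{i}", 0.5, 0.2) for i in range(3)]
        res = egger_test(eff)
        assert not res.detected and not res.evaluable

    def test_two_studies_not_evaluable(self):
        res = egger_test([StudyEffect("a", 0.1, 0.1), StudyEffect("b", 0.2, 0.2)])
        assert not res.evaluable and not res.detected

    def test_matches_ols_oracle_on_random_instances(self, rng):
        for i in range(100):
            eff = random_effects(rng, int(rng.integers(3, 10)), seed_offset=9000 + i)
            mine = egger_test(eff)
            x = np.array([1.0 / e.se for e in eff])
            y = np.array([e.log_or / e.se for e in eff])
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            assert mine.intercept == pytest.approx(float(fit.params[0]), abs=1e-10)
            assert mine.intercept_se == pytest.approx(float(fit.bse[0]), abs=1e-10)
            assert mine.p_value == pytest.approx(float(fit.pvalues[0]), abs=1e-10)

    def test_asymmetric_studies_detected(self):
        # large effects only in imprecise studies
        eff = [
            StudyEffect("a", 0.05, 0.05),
            StudyEffect("b", 0.10, 0.08),
            StudyEffect("c", 0.9, 0.45),
            StudyEffect("d", 1.2, 0.55),
            StudyEffect("e", 1.0, 0.5),
        ]
        assert egger_test(eff).detected


class TestMetaAnalyse:
    def test_recovers_simulated_effect(self):
        from credmeta import SimulationDesign, simulate_meta_dataset

        ds = simulate_meta_dataset(SimulationDesign(seed=7))
        res = meta_analyse(ds, "rs0000001", "CD", "dominant")
        assert res.ok
        lo, hi = res.pooled.ci95
        assert lo < 2.0 < hi

    def test_insufficient_studies_flagged(self):
        ds = Dataset(records=[make_record("s1")])
        res = meta_analyse(ds, "rs1", "CD", "dominant")
        assert res.status == "insufficient_studies"
        assert res.pooled is None

    def test_carrier_records_drop_from_recessive(self):
        recs = [make_record(f"s{i}") for i in range(3)]
        recs.append(make_record("s4", carrier_only=True, case=(50, 30), control=(70, 20)))
        ds = Dataset(records=recs)
        res = meta_analyse(ds, "rs1", "CD", "recessive")
        assert res.ok and len(res.effects) == 3
        assert ("s4", "carrier-only record, model inapplicable") in res.dropped

    def test_determinism(self, small_dataset):
        a = meta_analyse(small_dataset, "rs1", "CD", "dominant")
        b = meta_analyse(small_dataset, "rs1", "CD", "dominant")
        assert a.pooled == b.pooled and a.egger == b.egger

    def test_plot_data_exports(self, small_dataset):
        res = meta_analyse(small_dataset, "rs1", "CD", "dominant")
        fd = forest_data(res)
        assert fd["weight"].sum() == pytest.approx(1.0)
        assert set(funnel_data(res).columns) == {"study_id", "log_or", "se"}
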