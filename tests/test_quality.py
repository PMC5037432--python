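import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from credmeta import PowerSpec, exposure_prevalence, hwe_test, power_two_proportions
from credmeta.quality import hwe_exact_p


def exact_hwe_oracle(n_wtwt, n_wtvar, n_varvar):
    """Brute-force conditional HWE p-value in exact rational arithmetic."""
    n = n_wtwt + n_wtvar + n_varvar
    n_var = 2 * n_varvar + n_wtvar
    n_wt = 2 * n_wtwt + n_wtvar
    rare = min(n_var, n_wt)

    def prob(h):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        num = (
            Fraction(math.factorial(n))
            * 2**h
            * math.factorial(n_var)
            * math.factorial(n_wt)
        )
        den = (
            math.factorial(hom_rare)
            * math.factorial(h)
            * math.factorial(hom_common)
            * math.factorial(2 * n)
        )
        return num / den

    probs = {h: prob(h) for h in range(rare % 2, min(rare, 2 * n - rare) + 1, 2)}
    p_obs = probs[n_wtvar]
    return sum(p for p in probs.values() if p <= p_obs)


class TestHWE:
    def test_perfect_proportions(self):
        res = hwe_test((25, 50, 25))
        assert res.method == "chi_square"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert not res.violated

    def test_hand_computed_chi_square(self):
        # expected 7.5 / 15 / 7.5 -> X2 = 3.333, p ~ 0.068
        res = hwe_test((10, 10, 10))
        assert res.method == "chi_square"
        assert res.statistic == pytest.approx(10 / 3, rel=1e-12)
        assert res.p_value == pytest.approx(0.0679, abs=5e-4)
        assert not res.violated

    def test_two_diploid_enumeration(self):
        # 2 alleles of each kind in 2 diploids: P(het=0)=1/3, P(het=2)=2/3
        res = hwe_test((1, 0, 1))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 3, rel=1e-12)

    def test_carrier_only_not_evaluable(self):
        res = hwe_test(None)
        assert not res.evaluable and not res.violated

    def test_exact_matches_rational_oracle_exhaustively(self):
        """Every genotype table with up to 12 individuals, exactly."""
        n_max = 12
        for n in range(1, n_max + 1):
            for n_wtwt in range(n + 1):
                for n_wtvar in range(n - n_wtwt + 1):
                    n_varvar = n - n_wtwt - n_wtvar
                    want = float(exact_hwe_oracle(n_wtwt, n_wtvar, n_varvar))
                    got = hwe_exact_p(n_wtwt, n_wtvar, n_varvar)
                    assert got == pytest.approx(min(1.0, want), abs=1e-12)

    def test_exact_matches_rational_oracle_random(self, rng):
        count = 0
        while count < 120:
            n = int(rng.integers(3, 31))
            cuts = np.sort(rng.integers(0, n + 1, size=2))
            counts = (int(cuts[0]), int(cuts[1] - cuts[0]), int(n - cuts[1]))
            want = float(exact_hwe_oracle(*counts))
            assert hwe_exact_p(*counts) == pytest.approx(min(1.0, want), abs=1e-12)
            count += 1

    def test_chi_square_tracks_exact_in_decision_region(self, rng):
        """On HWE-true data with all expected counts >= 20, the chi-square
        approximation agrees with the exact test where it matters: within
        0.02 in the rejection-relevant tail (p <= 0.1), and on the
        violated/not-violated call outside a narrow band around alpha.
        (In the mid-p range the two-sided exact conditional p and the 1-df
        chi-square tail genuinely differ by more than 0.02 at these n.)"""
        checked = tail_checked = 0
        while checked < 60:
            q = float(rng.uniform(0.25, 0.75))
            n = 400
            counts = rng.multinomial(n, [(1 - q) ** 2, 2 * q * (1 - q), q**2])
            p_wt = (2 * counts[0] + counts[1]) / (2 * n)
            expected = (n * p_wt**2, 2 * n * p_wt * (1 - p_wt), n * (1 - p_wt) ** 2)
            if min(expected) < 20:
                continue
            chi = hwe_test(tuple(int(c) for c in counts))
            assert chi.method == "chi_square"
            exact_p = hwe_exact_p(*(int(c) for c in counts))
            if min(chi.p_value, exact_p) <= 0.1:
                assert abs(chi.p_value - exact_p) < 0.02
                tail_checked += 1
            if abs(exact_p - 0.05) > 0.02:
                assert chi.violated == (exact_p < 0.05)
            checked += 1
        assert tail_checked >= 3  # the tail case was actually exercised


class TestExposurePrevalence:
    @pytest.mark.parametrize(
        "f,model,expected",
        [
            (0.923, "dominant", 1 - 0.923**2),  # 0.1481
            (0.923, "recessive", 0.077**2),  # 0.0059
            (0.5, "additive2", 0.5),
            (0.6, "additive1", 2 * 0.6 * 0.4 / (0.36 + 2 * 0.6 * 0.4)),
        ],
    )
    def test_hwe_derivation(self, f, model, expected):
        assert exposure_prevalence(f, model) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("f", [0.0, 1.0])
    def test_degenerate_frequency_rejected(self, f):
        with pytest.raises(ValueError):
            exposure_prevalence(f, "dominant")


class TestPower:
    def test_null_alternative_gives_alpha(self):
        spec = PowerSpec(n_cases=500, n_controls=1000, p0=0.3, or_alt=1.0)
        assert power_two_proportions(spec) == pytest.approx(0.05, abs=1e-12)

    def test_published_endpoints(self):
        p0 = exposure_prevalence(0.923, "dominant")
        hi = power_two_proportions(PowerSpec(1158, 4766, p0, 0.32))
        assert round(hi, 2) == 1.00
        p0 = exposure_prevalence(0.923, "recessive")
        lo = power_two_proportions(PowerSpec(1158, 4766, p0, 0.97))
        assert round(lo, 2) == 0.05

    def test_monotone_in_effect_size_and_sample_size(self):
        grid = [1.1, 1.3, 1.6, 2.0, 3.0]
        powers = [
            power_two_proportions(PowerSpec(300, 600, 0.2, or_))
            for or_ in grid
        ]
        assert powers == sorted(powers)
        protective = [
            power_two_proportions(PowerSpec(300, 600, 0.2, 1 / or_))
            for or_ in grid
        ]
        assert protective == sorted(protective)
        sizes = [(100, 200), (300, 600), (1000, 2000)]
        by_n = [power_two_proportions(PowerSpec(n1, n2, 0.2, 1.5)) for n1, n2 in sizes]
        assert by_n == sorted(by_n)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        p0=st.floats(0.01, 0.95),
        or_=st.floats(0.2, 5.0),
        n1=st.integers(20, 3000),
    )
    def test_power_bounded_and_above_half_alpha(self, p0, or_, n1):
        power = power_two_proportions(PowerSpec(n1, 2 * n1, p0, or_))
        assert 0.025 - 1e-12 <= power <= 1.0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(100, 100, p0=0.0, or_alt=1.5)
        with pytest.raises(ValueError):
            PowerSpec(100, 100, p0=0.5, or_alt=-1.0)
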