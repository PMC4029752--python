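import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from natsirna.stats import (
    CountContrast,
    ac_p_value,
    ac_point_probability,
    call_heat_response,
    call_strand_bias,
    format_ratio,
    ratio_with_conventions,
)

from oracles import (
    exact_lower_tail,
    exact_point_prob,
    exact_two_sided,
    exact_upper_tail,
)


class TestPointProbability:
    def test_zero_zero_equal_totals_is_half(self):
        assert ac_point_probability(CountContrast(0, 0, 1, 1)) == pytest.approx(0.5)

    def test_symmetric_five_five(self):
        # C(10,5)/2^11 = 252/2048
        p = ac_point_probability(CountContrast(5, 5, 1, 1))
        assert p == pytest.approx(252 / 2048, rel=1e-12)

    def test_unequal_totals_closed_form(self):
        # x=2, y=0, r=2 -> (1+2)^-3 = 1/27
        p = ac_point_probability(CountContrast(2, 0, 1000, 2000))
        assert p == pytest.approx(1 / 27, rel=1e-12)

    def test_invalid_totals_rejected(self):
        with pytest.raises(ValueError):
            CountContrast(1, 1, 0, 1)

    @pytest.mark.parametrize("n1,n2", [(10_000, 10_000), (10_000, 5_000), (7_000, 14_000)])
    def test_matches_exact_oracle_on_grid(self, n1, n2):
        for x in range(0, 21, 4):
            for y in range(0, 21, 3):
                got = ac_point_probability(CountContrast(x, y, n1, n2))
                want = float(exact_point_prob(x, y, n1, n2))
                assert got == pytest.approx(want, rel=1e-12)

    def test_distribution_normalizes_over_y(self):
        for x in (0, 3, 40):
            for n1, n2 in ((1e7, 1e7), (1e7, 2e7)):
                total, y = 0.0, 0
                while total < 1 - 1e-9:
                    total += ac_point_probability(CountContrast(x, y, n1, n2))
                    y += 1
                    assert y < 5000
                assert total == pytest.approx(1.0, abs=1e-9)


class TestPValue:
    def test_lower_tail_at_zero_is_point_mass(self):
        c = CountContrast(7, 0, 1e6, 1e6)
        assert ac_p_value(c, "lower") == pytest.approx(
            ac_point_probability(c), rel=1e-12
        )

    def test_tails_share_the_point_mass(self):
        c = CountContrast(5, 5, 1, 1)
        lo, up = ac_p_value(c, "lower"), ac_p_value(c, "upper")
        assert lo + up == pytest.approx(1 + ac_point_probability(c), rel=1e-12)

    def test_two_sided_capped_at_one(self):
        assert ac_p_value(CountContrast(5, 5, 1, 1), "two") == 1.0

    @pytest.mark.parametrize("n1,n2", [(100, 100), (100, 50), (100, 200)])
    def test_tails_match_exact_oracle(self, n1, n2):
        for x in range(0, 25, 5):
            for y in range(0, 25, 5):
                c = CountContrast(x, y, n1, n2)
                assert ac_p_value(c, "lower") == pytest.approx(
                    float(exact_lower_tail(x, y, n1, n2)), rel=1e-12
                )
                assert ac_p_value(c, "upper") == pytest.approx(
                    float(exact_upper_tail(x, y, n1, n2)), rel=1e-12
                )
                assert ac_p_value(c, "two") == pytest.approx(
                    float(exact_two_sided(x, y, n1, n2)), rel=1e-12
                )

    @given(x=st.integers(0, 200), y=st.integers(0, 200))
    @settings(derandomize=True, max_examples=200)
    def test_symmetry_with_equal_totals(self, x, y):
        p_xy = ac_point_probability(CountContrast(x, y, 5e6, 5e6))
        p_yx = ac_point_probability(CountContrast(y, x, 5e6, 5e6))
        assert p_xy == pytest.approx(p_yx, rel=1e-10)

    def test_never_exactly_zero_for_finite_counts(self):
        assert ac_p_value(CountContrast(500, 0, 1, 1), "two") > 0.0


class TestRatioConventions:
    def test_inf_when_denominator_zero(self):
        assert ratio_with_conventions(10, 0) == math.inf
        assert format_ratio(math.inf) == "INF"

    def test_zero_when_numerator_zero(self):
        assert ratio_with_conventions(0, 8) == 0.0
        assert format_ratio(0.0) == "0.00"

    def test_undefined_when_both_zero(self):
        assert ratio_with_conventions(0, 0) is None
        assert format_ratio(None) == "NA"


class TestCallStrandBias:
    def test_all_forward_reads_is_inf_and_biased(self):
        call = call_strand_bias(100, 0)
        assert call.ratio == math.inf
        assert call.biased

    def test_all_reverse_reads_is_zero_ratio(self):
        call = call_strand_bias(0, 80)
        assert call.ratio == 0.0
        assert call.biased

    def test_symmetric_counts_not_biased(self):
        call = call_strand_bias(4, 4)
        assert call.ratio == 1.0
        assert not call.biased

    def test_extreme_ratio_without_significance_not_biased(self):
        # 3:1 exceeds 2-fold but tiny counts give p > 0.01
        call = call_strand_bias(3, 1)
        assert call.ratio == 3.0
        assert call.p_value > 0.01
        assert not call.biased

    def test_both_zero_undefined_and_not_biased(self):
        call = call_strand_bias(0, 0)
        assert call.ratio is None and not call.biased

    @given(fr=st.integers(0, 500), rr=st.integers(0, 500))
    @settings(derandomize=True, max_examples=200)
    def test_swapping_strands_gives_reciprocal_ratio_equal_p(self, fr, rr):
        a, b = call_strand_bias(fr, rr), call_strand_bias(rr, fr)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-10)
        if a.ratio not in (None, 0) and not math.isinf(a.ratio):
            assert b.ratio == pytest.approx(1 / a.ratio)
        assert a.biased == b.biased


class TestCallHeatResponse:
    LIBS = {"NT1": 11.25e6, "HT1": 14.67e6, "NT2": 14.61e6, "HT2": 12.77e6}

    def test_concordant_upregulation_called(self):
        totals = {"NT1": 100, "HT1": 600, "NT2": 120, "HT2": 500}
        call = call_heat_response(totals, self.LIBS)
        assert call.direction == "up" and call.significant
        assert call.ratio_rep1 > 2 and call.ratio_rep2 > 2

    def test_concordant_downregulation_called(self):
        totals = {"NT1": 500, "HT1": 20, "NT2": 400, "HT2": 40}
        call = call_heat_response(totals, self.LIBS)
        assert call.direction == "down" and call.significant

    def test_discordant_replicates_not_called(self):
        # one replicate trebles, the other only x1.5 -> concordance fails
        totals = {"NT1": 100, "HT1": 390, "NT2": 200, "HT2": 262}
        call = call_heat_response(totals, self.LIBS)
        assert call.direction == "none" and not call.significant

    def test_heat_only_expression_gives_inf_ratio(self):
        totals = {"NT1": 0, "HT1": 300, "NT2": 0, "HT2": 200}
        call = call_heat_response(totals, self.LIBS)
        assert math.isinf(call.ratio_rep1) and math.isinf(call.ratio_rep2)
        assert call.direction == "up" and call.significant

    def test_fold_change_without_significance_not_called(self):
        totals = {"NT1": 1, "HT1": 4, "NT2": 1, "HT2": 4}
        call = call_heat_response(totals, self.LIBS)
        assert not call.significant

    def test_missing_replicate_rejected(self):
        with pytest.raises(ValueError, match="NT2"):
            call_heat_response(
                {"NT1": 1, "HT1": 2, "HT2": 3}, self.LIBS
            )

    def test_ratio_uses_rp10m_normalized_totals(self):
        # equal raw counts but deeper HT libraries -> normalized ratio < 1
        libs = {"NT1": 1e7, "HT1": 4e7, "NT2": 1e7, "HT2": 4e7}
        totals = {"NT1": 100, "HT1": 100, "NT2": 100, "HT2": 100}
        call = call_heat_response(totals, libs)
        assert call.ratio_rep1 == pytest.approx(0.25)


def test_null_calibration_small_monte_carlo():
    """Type-I error of the two-sided test stays at or below alpha under a
    Poisson null (quick check; the full 1e5-contrast version runs in the
    acceptance suite)."""
    from natsirna.stats import ac_p_value_array

    rng = np.random.default_rng(2024)
    n1, n2, lam = 1.1e7, 1.4e7, 30.0
    x = rng.poisson(lam * n1 / 1e7, size=20_000)
    y = rng.poisson(lam * n2 / 1e7, size=20_000)
    p = ac_p_value_array(x, y, n1, n2)
    rate = float(np.mean(p < 0.01))
    sigma = math.sqrt(0.01 * 0.99 / x.size)
    assert rate <= 0.01 + 3 * sigma
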