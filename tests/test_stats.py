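from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from assemblymotifs import (
    AreaPairStats,
    binom_direction_test,
    binom_loop_test,
    expected_loop_prob,
    int_ext_index,
    p_looplike,
    p_looplike_structured,
    p_pairs_ext,
    p_pairs_int,
    pool_sessions,
    rank_areas,
)
from assemblymotifs.stats import _loop_denominator

from .oracles import (
    enumerate_internal_pairs,
    enumerate_loop_chains,
    exact_binom_minlike_two_sided,
    exact_binom_symmetric_two_sided,
)


class TestProbabilities:
    def test_pairs_ext_arithmetic(self):
        assert p_pairs_ext(0, 5, 7) == 0
        assert p_pairs_ext(6, 3, 4) == 0.5
        assert p_pairs_ext(12, 3, 4) == 1.0  # saturation

    def test_pairs_int_arithmetic(self):
        assert p_pairs_int(0, 10) == 0
        assert p_pairs_int(3, 4) == 0.5
        with pytest.raises(ValueError):
            p_pairs_int(1, 1)

    def test_looplike_arithmetic(self):
        assert p_looplike(0, 4, 5) == 0
        assert p_looplike(3, 3, 2) == pytest.approx(1 / 3)
        with pytest.raises(ValueError):
            p_looplike(0, 1, 1)

    def test_looplike_structured_arithmetic(self):
        assert p_looplike_structured(0, 3, 2) == 0
        assert p_looplike_structured(6, 3, 2) == 1.0  # saturation
        with pytest.raises(ValueError):
            p_looplike_structured(1, 1, 3)

    def test_denominators_match_exhaustive_enumeration(self):
        # all configurations with up to 6 units per area
        for n_a in range(1, 7):
            assert comb(n_a, 2) == enumerate_internal_pairs(n_a)
            for n_b in range(1, 7):
                aba, bab = enumerate_loop_chains(n_a, n_b)
                assert _loop_denominator(n_a, n_b) == aba + bab
                assert n_a * n_b * (n_a - 1) == aba
                # each unordered loop-like triple supports two chain orders
                assert aba % 2 == 0 and aba // 2 == comb(n_a, 2) * n_b


class TestIntExtIndex:
    def test_equal_probabilities_give_half(self):
        assert int_ext_index(0.01, 0.01) == 0.5

    def test_boundaries(self):
        assert int_ext_index(0.3, 0.0) == 1.0
        assert int_ext_index(0.0, 0.3) == 0.0

    def test_undefined_when_both_zero(self):
        with pytest.raises(ValueError):
            int_ext_index(0.0, 0.0)


class TestExpectedLoopProb:
    def test_degenerate_single_partner_unit(self):
        assert expected_loop_prob(2, 1) == 1.0  # only A->B->A possible

    def test_symmetric_areas(self):
        assert expected_loop_prob(5, 5) == 0.5

    def test_matches_enumeration(self):
        for n_a in range(1, 7):
            for n_b in range(1, 7):
                if n_a + n_b < 3:
                    continue
                aba, bab = enumerate_loop_chains(n_a, n_b)
                assert expected_loop_prob(n_a, n_b) == pytest.approx(aba / (aba + bab))

    @given(n_a=st.integers(1, 50), n_b=st.integers(1, 50))
    def test_structure_probabilities_sum_to_one(self, n_a, n_b):
        if n_a + n_b < 3:
            return
        assert expected_loop_prob(n_a, n_b) + expected_loop_prob(n_b, n_a) == pytest.approx(1.0)


class TestDirectionTest:
    def test_symmetric_counts_give_p_one(self):
        assert binom_direction_test(5, 5).p_value == 1.0

    def test_eight_two_exact_value(self):
        res = binom_direction_test(8, 2)
        assert res.p_value == pytest.approx(0.109375, abs=1e-12)
        assert res.p_value == pytest.approx(exact_binom_symmetric_two_sided(8, 10), abs=1e-12)

    def test_below_threshold_not_tested(self):
        res = binom_direction_test(4, 3)
        assert not res.tested and res.p_value is None and res.n == 7

    @given(a=st.integers(0, 40), b=st.integers(0, 40))
    def test_symmetric_in_arguments(self, a, b):
        ra, rb = binom_direction_test(a, b), binom_direction_test(b, a)
        assert ra.tested == rb.tested
        if ra.tested:
            assert ra.p_value == pytest.approx(rb.p_value, abs=1e-12)

    @given(a=st.integers(0, 30), b=st.integers(0, 30))
    def test_matches_exact_tail_sum(self, a, b):
        res = binom_direction_test(a, b, min_total=0)
        assert res.p_value == pytest.approx(
            exact_binom_symmetric_two_sided(a, a + b), abs=1e-12
        )


class TestLoopTest:
    def test_observation_at_null_gives_p_one(self):
        res = binom_loop_test(6, 12, 4, 4)  # p0 = 0.5, observed exactly at it
        assert res.p_value == 1.0

    def test_degenerate_null_prob_one(self):
        res = binom_loop_test(12, 12, 2, 1)  # only A->B->A possible: p0 = 1
        assert res.p_value == 1.0

    def test_matches_minlike_oracle(self):
        res = binom_loop_test(9, 12, 4, 4)
        assert res.null_prob == 0.5
        assert res.p_value == pytest.approx(
            exact_binom_minlike_two_sided(9, 12, 0.5), abs=1e-12
        )

    def test_asymmetric_null_matches_oracle(self):
        res = binom_loop_test(11, 15, 5, 3)  # p0 = 4/6
        assert res.p_value == pytest.approx(
            exact_binom_minlike_two_sided(11, 15, 4 / 6), abs=1e-12
        )

    def test_doubled_one_tail_option(self):
        from scipy.stats import binom as binom_dist

        res = binom_loop_test(11, 15, 5, 3, method="doubled")
        p0 = 4 / 6
        want = min(1.0, 2 * min(binom_dist.cdf(11, 15, p0), binom_dist.sf(10, 15, p0)))
        assert res.p_value == pytest.approx(want, abs=1e-12)

    def test_below_threshold_not_tested(self):
        assert not binom_loop_test(3, 9, 4, 4).tested

    def test_type_one_error_at_most_nominal(self):
        # simulated null structure draws at p0: rejection rate of the exact
        # test stays at or below alpha
        rng = np.random.default_rng(123)
        n_a, n_b, n_total = 4, 3, 30
        p0 = expected_loop_prob(n_a, n_b)
        draws = rng.binomial(n_total, p0, size=2000)
        rej = sum(
            binom_loop_test(int(k), n_total, n_a, n_b).p_value < 0.05 for k in draws
        )
        assert rej / 2000 <= 0.05


def aps(n_ext, n_a, n_b, session="s1", **kw):
    return AreaPairStats(
        "ZI", "MS", n_a, n_b, n_pairs_ext=n_ext, n_pairs_sync=n_ext,
        sessions=(session,), **kw
    )


class TestPooling:
    def test_single_session_is_identity(self):
        s = aps(3, 4, 5)
        assert pool_sessions([s]).p_ext == s.p_ext

    def test_sums_numerators_and_denominators(self):
        # (1 of 10) + (1 of 40) pools to 2/50 = 0.04, not mean(0.1, 0.025)
        s1 = aps(1, 2, 5)   # denominator 10
        s2 = aps(1, 5, 8)   # denominator 40
        pooled = pool_sessions([s1, s2])
        assert pooled.p_ext == pytest.approx(0.04)
        assert pooled.p_ext != pytest.approx(np.mean([s1.p_ext, s2.p_ext]))

    def test_order_invariant_and_associative(self):
        parts = [aps(1, 2, 5, "a"), aps(3, 3, 4, "b"), aps(0, 4, 4, "c")]
        p1 = pool_sessions(parts)
        p2 = pool_sessions(parts[::-1])
        p3 = pool_sessions([pool_sessions(parts[:2]), parts[2]])
        assert p1.p_ext == p2.p_ext == p3.p_ext
        assert p1.denom_ext == p2.denom_ext == p3.denom_ext

    def test_empty_and_mismatched_inputs(self):
        with pytest.raises(ValueError):
            pool_sessions([])
        other = AreaPairStats("ZI", "CA1", 2, 2)
        with pytest.raises(ValueError):
            pool_sessions([aps(0, 2, 2), other])


class TestRanking:
    def test_descending_with_alphabetical_ties(self):
        rows = [
            AreaPairStats("ZI", "MS", 2, 5, n_pairs_ext=1, n_pairs_sync=1),
            AreaPairStats("ZI", "CA1", 2, 5, n_pairs_ext=3, n_pairs_sync=3),
            AreaPairStats("ZI", "LGd", 2, 5, n_pairs_ext=1, n_pairs_sync=1),
        ]
        df = rank_areas(rows, "pairs")
        assert list(df["area"]) == ["CA1", "LGd", "MS"]

    def test_single_area(self):
        df = rank_areas([aps(1, 2, 2)], "pairs")
        assert list(df["area"]) == ["MS"]

    def test_unknown_metric(self):
        with pytest.raises(ValueError):
            rank_areas([aps(1, 2, 2)], "hubs")
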