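from itertools import product

import pytest

from assemblymotifs import (
    AssemblyPattern,
    classify_assemblies,
    classify_pair,
    classify_triplet,
    coverage,
    loop_membership_crosstab,
    pairwise_support,
)
from assemblymotifs.motifs import COVERAGE_CATEGORIES, PAIR_CLASSES, TRIPLET_CLASSES


def pair(u1, a1, u2, a2, lag, bin_size=0.03):
    return AssemblyPattern((u1, u2), (a1, a2), (0, lag), bin_size, 50, 1e-6)


def triplet(units, areas, lags, bin_size=0.03):
    return AssemblyPattern(tuple(units), tuple(areas), tuple(lags), bin_size, 40, 1e-6)


class TestClassifyPair:
    def test_from_focal_with_60ms_delay(self):
        a = pair("zi_1", "ZI", "lgd_1", "LGd", 2, 0.03)
        rec = classify_pair(a, "ZI")
        assert rec.klass == "pair_from_focal"
        assert rec.partner_area == "LGd"
        assert a.delays_s[1] == 0.06

    def test_to_focal_with_80ms_delay(self):
        a = pair("snr_1", "SNr", "zi_1", "ZI", 4, 0.02)
        rec = classify_pair(a, "ZI")
        assert rec.klass == "pair_to_focal"
        assert a.delays_s[1] == 0.08

    def test_internal_synchronous(self):
        rec = classify_pair(pair("zi_1", "ZI", "zi_2", "ZI", 0), "ZI")
        assert rec.klass == "pair_internal_focal" and rec.synchronous

    def test_internal_other_directional(self):
        rec = classify_pair(pair("ms_1", "MS", "ms_2", "MS", 3), "ZI")
        assert rec.klass == "pair_internal_other" and not rec.synchronous

    def test_external_between_two_nonfocal_areas(self):
        rec = classify_pair(pair("ms_1", "MS", "ca1_1", "CA1", 1), "ZI")
        assert rec.klass == "pair_external_other"

    def test_cross_area_synchronous(self):
        rec = classify_pair(pair("zi_1", "ZI", "ms_1", "MS", 0), "ZI")
        assert rec.klass == "pair_synchronous"

    def test_rejects_triplet(self):
        with pytest.raises(ValueError):
            classify_pair(triplet("abc", "ZZZ", (0, 1, 2)), "ZI")


class TestClassifyTriplet:
    def test_focal_loop(self):
        a = triplet(("zi_1", "ms_3", "zi_7"), ("ZI", "MS", "ZI"), (0, 1, 2))
        assert classify_triplet(a, "ZI").klass == "triplet_loop_focal"

    def test_external_loop(self):
        a = triplet(("ms_1", "zi_2", "ms_4"), ("MS", "ZI", "MS"), (0, 2, 5))
        rec = classify_triplet(a, "ZI")
        assert rec.klass == "triplet_loop_external" and rec.partner_area == "MS"

    def test_synchronous_subactivation_is_non_loop(self):
        a = triplet(("zi_1", "ms_1", "zi_2"), ("ZI", "MS", "ZI"), (0, 0, 3))
        assert classify_triplet(a, "ZI").klass == "triplet_non_loop"

    def test_wrong_chain_is_non_loop(self):
        a = triplet(("ms_1", "ms_2", "zi_1"), ("MS", "MS", "ZI"), (0, 1, 2))
        assert classify_triplet(a, "ZI").klass == "triplet_non_loop"

    def test_three_area_triplet_is_non_loop(self):
        a = triplet(("zi_1", "ms_1", "ca_1"), ("ZI", "MS", "CA1"), (0, 1, 2))
        assert classify_triplet(a, "ZI").klass == "triplet_non_loop"

    def test_agrees_with_brute_force_rule_checker(self):
        # exhaustive over canonical lag structures from {0,1,2} and all
        # 2-area assignments
        lag_structs = [
            (0, a, b) for a in range(3) for b in range(3) if 0 <= a <= b
        ]
        for lags, areas in product(lag_structs, product(("ZI", "X"), repeat=3)):
            a = triplet(("u1", "u2", "u3"), areas, lags)
            got = classify_triplet(a, "ZI").klass
            loop = (
                len(set(lags)) == 3
                and areas[0] == areas[2] != areas[1]
            )
            if loop and areas[0] == "ZI":
                want = "triplet_loop_focal"
            elif loop:
                want = "triplet_loop_external"
            else:
                want = "triplet_non_loop"
            assert got == want, (lags, areas)

    def test_classification_is_total(self):
        # every order-2/3 assembly gets exactly one class from the taxonomy
        a2 = pair("zi_1", "ZI", "ms_1", "MS", 1)
        a3 = triplet(("zi_1", "ms_1", "zi_2"), ("ZI", "MS", "ZI"), (0, 1, 2))
        recs = classify_assemblies([a2, a3], "ZI")
        assert recs[0].klass in PAIR_CLASSES
        assert recs[1].klass in TRIPLET_CLASSES


class TestPairwiseSupport:
    trip = triplet(("a", "b", "c"), ("ZI", "MS", "ZI"), (0, 1, 2))

    def test_both_chain_pairs_present(self):
        pairs = [pair("a", "ZI", "b", "MS", 1), pair("b", "MS", "c", "ZI", 1)]
        assert pairwise_support(self.trip, pairs)

    def test_first_chain_pair_missing(self):
        pairs = [pair("b", "MS", "c", "ZI", 1), pair("a", "ZI", "c", "ZI", 2)]
        assert not pairwise_support(self.trip, pairs)

    def test_non_adjacent_pair_does_not_count(self):
        # only chain-adjacent (first-second, second-third) pairs matter
        pairs = [pair("a", "ZI", "c", "ZI", 2)]
        assert not pairwise_support(self.trip, pairs)


def _many_area_session(make_session, n_ext, linked):
    spikes = {"zi_0": ("ZI", [0.1]), "zi_1": ("ZI", [0.2])}
    for i in range(n_ext):
        spikes[f"x{i}_0"] = (f"X{i:02d}", [0.3])
    s = make_session(spikes, 10.0)
    recs = classify_assemblies(
        [pair("zi_0", "ZI", f"x{i}_0", f"X{i:02d}", 1) for i in linked], "ZI"
    )
    return s, recs


class TestCoverage:
    def test_unit_in_no_assemblies(self, make_session):
        s, _ = _many_area_session(make_session, 3, [])
        assert coverage("zi_0", [], s).category == "no_int_no_ext"

    def test_only_internal(self, make_session):
        s, _ = _many_area_session(make_session, 3, [])
        recs = classify_assemblies([pair("zi_0", "ZI", "zi_1", "ZI", 0)], "ZI")
        assert coverage("zi_0", recs, s).category == "only_int"

    def test_all_external(self, make_session):
        s, recs = _many_area_session(make_session, 3, range(3))
        assert coverage("zi_0", recs, s).category == "all_ext"

    def test_at_least_half_rule_n13_k7(self, make_session):
        s, recs = _many_area_session(make_session, 13, range(7))
        c = coverage("zi_0", recs, s)
        assert c.category == "ge_half_not_all"
        assert (c.n_partner_areas, c.n_areas_available) == (7, 13)

    def test_less_than_half(self, make_session):
        s, recs = _many_area_session(make_session, 13, range(6))
        assert coverage("zi_0", recs, s).category == "lt_half_ext_at_least_1"

    def test_rejects_non_focal_unit(self, make_session):
        s, _ = _many_area_session(make_session, 3, [])
        with pytest.raises(ValueError):
            coverage("x0_0", [], s)


class TestCrosstab:
    def test_no_triplets_puts_everyone_in_non_loop_branch(self, make_session):
        s, recs = _many_area_session(make_session, 3, range(2))
        tab = loop_membership_crosstab(recs, s)
        assert tab["branches"]["loop"]["n_units"] == 0
        assert tab["branches"]["non_loop"]["n_units"] == 2

    def test_fractions_partition_each_branch(self, make_session):
        s, recs = _many_area_session(make_session, 3, range(2))
        trip = classify_assemblies(
            [triplet(("zi_0", "x0_0", "zi_1"), ("ZI", "X00", "ZI"), (0, 1, 2))], "ZI"
        )
        tab = loop_membership_crosstab(list(recs) + trip, s)
        for branch in ("loop", "non_loop"):
            if tab["branches"][branch]["n_units"]:
                assert sum(tab["branches"][branch]["fractions"].values()) == pytest.approx(1.0)
        assert set(tab["branches"]["loop"]["counts"]) == set(COVERAGE_CATEGORIES)
        # planted loop members landed in the loop branch
        assert tab["branches"]["loop"]["n_units"] == 2
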