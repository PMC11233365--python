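"""Fair proportion and equal splits: values, matrices, axioms."""

from fractions import Fraction as F

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylodiv import (
    ClusterWeighting,
    check_downward_continuity,
    check_properties,
    equal_splits,
    equal_splits_coefficients,
    fair_proportion,
    index_matrix,
    make_cluster_system,
    restrict,
)
from phylodiv.datasets import (
    neutrality_counterexample,
    random_cluster_system,
    random_cluster_weighting,
)


class TestFairProportion:
    def test_example_vector(self, rooted_example):
        fp = fair_proportion(rooted_example)
        assert fp.as_tuple() == (F(5), F(4), F(7), F(3), F(6))

    def test_single_cluster_concentrates_on_members(self):
        cs = make_cluster_system("abc", [{"a"}])
        w = ClusterWeighting(cs, {frozenset("a"): F(7, 3)})
        fp = fair_proportion(w)
        assert fp["a"] == F(7, 3) and fp["b"] == 0 and fp["c"] == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_matrix_product(self, seed):
        """Eq-by-definition summation equals Gamma applied to omega."""
        cs = random_cluster_system(5, 6, seed)
        w = random_cluster_weighting(cs, seed + 100)
        gamma = index_matrix("fair_proportion", cs)
        assert gamma.apply(w) == fair_proportion(w)

    @pytest.mark.parametrize("seed", range(8))
    def test_complete_on_random_systems(self, seed):
        cs = random_cluster_system(6, 9, seed)
        w = random_cluster_weighting(cs, seed + 50)
        assert fair_proportion(w).total() == w.total()

    @given(st.lists(st.integers(-30, 30), min_size=6, max_size=6),
           st.lists(st.integers(-30, 30), min_size=6, max_size=6),
           st.integers(-5, 5))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_linearity(self, w1, w2, a):
        """FP(a*w1 + w2) = a*FP(w1) + FP(w2), exactly."""
        cs = random_cluster_system(4, 6, 3)
        order = cs.ordered
        omega1 = ClusterWeighting(cs, dict(zip(order, w1)))
        omega2 = ClusterWeighting(cs, dict(zip(order, w2)))
        combo = ClusterWeighting(
            cs, {c: a * omega1.weight(c) + omega2.weight(c) for c in order}
        )
        assert fair_proportion(combo) == a * fair_proportion(omega1) + fair_proportion(omega2)


class TestEqualSplits:
    def test_coefficients_on_overlapping_children(self):
        cs = make_cluster_system(
            "abcde", [frozenset("abcde"), frozenset("abc"), frozenset("cd")]
        )
        m = equal_splits_coefficients(cs)
        assert m[(frozenset("abcde"), "e")] == F(1, 3)

    def test_coefficients_childless_cluster_is_uniform(self):
        cs = make_cluster_system("abcd", [{"a", "b", "c"}])
        m = equal_splits_coefficients(cs)
        assert m[(frozenset("abc"), "a")] == F(1, 3)
        assert m[(frozenset("abc"), "d")] == 0

    def test_example_hierarchy_coefficients(self, rooted_example):
        m = equal_splits_coefficients(rooted_example.system)
        cde = frozenset("cde")
        assert m[(cde, "c")] == F(1, 2)
        assert m[(cde, "d")] == F(1, 4)
        assert m[(cde, "e")] == F(1, 4)

    def test_example_vector(self, rooted_example):
        es = equal_splits(rooted_example)
        assert es.as_tuple() == (F(5), F(4), F(15, 2), F(11, 4), F(23, 4))
        assert es.total() == 25

    def test_single_cluster_reduces_to_fair_proportion(self):
        cs = make_cluster_system("abc", [{"a", "b"}])
        w = ClusterWeighting(cs, {frozenset("ab"): F(5)})
        assert equal_splits(w) == fair_proportion(w)

    @pytest.mark.parametrize("seed", range(8))
    def test_coefficient_rows_sum_to_one(self, seed):
        cs = random_cluster_system(8, 10, seed)
        m = equal_splits_coefficients(cs)
        for c in cs:
            assert sum(m[(c, x)] for x in cs.taxa) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_complete_on_random_systems(self, seed):
        cs = random_cluster_system(6, 8, seed)
        w = random_cluster_weighting(cs, seed + 7)
        assert equal_splits(w).total() == w.total()


class TestIndexMatrix:
    def test_fair_proportion_row(self, rooted_example):
        gamma = index_matrix("fair_proportion", rooted_example.system)
        assert gamma.row(frozenset("cde")) == (0, 0, F(1, 3), F(1, 3), F(1, 3))

    def test_equal_splits_rows_sum_to_one(self, rooted_example):
        gamma = index_matrix("equal_splits", rooted_example.system)
        assert all(gamma.row_sum(c) == 1 for c in gamma.rows)

    def test_unknown_index_name(self, rooted_example):
        with pytest.raises(ValueError):
            index_matrix("banana", rooted_example.system)

    def test_equal_splits_matrix_reproduces_index(self, rooted_example):
        gamma = index_matrix("equal_splits", rooted_example.system)
        assert gamma.apply(rooted_example) == equal_splits(rooted_example)


class TestRestriction:
    def test_members_lose_exactly_their_share(self, rooted_example):
        c = frozenset("cde")
        before = fair_proportion(rooted_example)
        after = fair_proportion(restrict(rooted_example, c))
        share = rooted_example.weight(c) / len(c)
        for x in rooted_example.system.taxa:
            expected = before[x] - (share if x in c else 0)
            assert after[x] == expected

    def test_matrix_restriction_is_row_deletion(self, rooted_example):
        c = frozenset("ab")
        gamma = index_matrix("fair_proportion", rooted_example.system)
        gamma_star = index_matrix("fair_proportion", rooted_example.system.without(c))
        assert gamma.drop_row(c) == gamma_star

    def test_cannot_remove_last_cluster(self):
        cs = make_cluster_system("ab", [{"a"}])
        w = ClusterWeighting(cs, {frozenset("a"): 1})
        with pytest.raises(ValueError):
            restrict(w, frozenset("a"))

    def test_rankings_can_change_under_hierarchical_restriction(self):
        """On a non-hierarchy, deleting different overlap-breaking clusters
        can produce different taxon rankings."""
        cs = make_cluster_system("abcd", [{"a", "b"}, {"b", "c"}, {"b", "c", "d"}])
        w = ClusterWeighting(
            cs,
            {frozenset("ab"): 2, frozenset("bc"): 4, frozenset("bcd"): 3},
        )
        r_full = [x for x, _ in fair_proportion(w).ranking()]
        r_drop = [
            x for x, _ in fair_proportion(restrict(w, frozenset("bc"))).ranking()
        ]
        assert r_full != r_drop


class TestAxiomCheckers:
    def test_fair_proportion_passes_all_axioms(self, rooted_example):
        cs = rooted_example.system
        report = check_properties(index_matrix("fair_proportion", cs), cs)
        assert report.complete and report.neutral and report.descendant_diversity
        assert report.notes == []

    def test_counterexample_passes_axioms_but_is_not_fair_proportion(self):
        cs, gamma = neutrality_counterexample()
        report = check_properties(gamma, cs)
        assert report.complete and report.neutral and report.descendant_diversity
        assert gamma != index_matrix("fair_proportion", cs)

    def test_incomplete_row_is_flagged_with_witness(self):
        cs = make_cluster_system("ab", [{"a", "b"}])
        from phylodiv import IndexMatrix

        gamma = IndexMatrix(
            cs.ordered, cs.taxa, {(frozenset("ab"), "a"): 1, (frozenset("ab"), "b"): 1}
        )
        report = check_properties(gamma, cs)
        assert not report.complete
        assert any("sums to 2" in note for note in report.notes)

    def test_fair_proportion_is_downward_continuous(self, rooted_example):
        cs = rooted_example.system
        gamma = index_matrix("fair_proportion", cs)
        for c in cs:
            gamma_star = index_matrix("fair_proportion", cs.without(c))
            assert check_downward_continuity(gamma, gamma_star, c)

    def test_equal_splits_breaks_downward_continuity_on_chains(self):
        """Deleting a middle cluster changes the child structure, so the
        reduced-system coefficients differ from simple row deletion."""
        cs = make_cluster_system("abc", [{"a"}, {"a", "b"}, {"a", "b", "c"}])
        mid = frozenset("ab")
        gamma = index_matrix("equal_splits", cs)
        gamma_star = index_matrix("equal_splits", cs.without(mid))
        assert not check_downward_continuity(gamma, gamma_star, mid)
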