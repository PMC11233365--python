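"""Circular split systems, incidence matrices, right inverses, Psi_R."""

from fractions import Fraction as F

import pytest
import sympy

from phylodiv import (
    CircularOrdering,
    RightInverse,
    distances,
    full_circular_system,
    full_gamma_entry,
    full_gamma_matrix,
    full_right_inverse,
    is_circular,
    make_split,
    pair_incidence,
    psi_r,
    psi_r_matrix,
    restricted_psi,
)
from phylodiv.datasets import (
    random_circular_split_system,
    random_split_weighting,
    taxon_labels,
)


def sympy_right_inverse(ss):
    """Oracle: exact right inverse of M(ss) via sympy (pseudo-solve for
    full systems this is the plain matrix inverse)."""
    m = pair_incidence(ss)
    mat = sympy.Matrix([m.row(s) for s in m.splits])
    inv = mat.inv()  # square only: used for full systems
    entries = {}
    for j, pair in enumerate(m.pairs):
        for k, s in enumerate(m.splits):
            v = inv[j, k]
            if v != 0:
                entries[(pair, s)] = F(int(v.p), int(v.q))
    return RightInverse(ss, entries)


class TestFullCircularSystem:
    @pytest.mark.parametrize("n", range(3, 9))
    def test_size_is_n_choose_2(self, n):
        theta = CircularOrdering(taxon_labels(n))
        assert len(full_circular_system(theta)) == n * (n - 1) // 2

    def test_n4_splits_by_enumeration(self):
        theta = CircularOrdering("abcd")
        ss = full_circular_system(theta)
        taxa = theta.taxa
        expected = {
            make_split(taxa, p)
            for p in [{"a"}, {"b"}, {"c"}, {"a", "b"}, {"b", "c"}, {"a", "b", "c"}]
        }
        assert ss.splits == expected

    def test_every_member_is_circular(self):
        theta = CircularOrdering("abcde")
        ss = full_circular_system(theta)
        assert is_circular(ss, theta)

    def test_minimum_size_guard(self):
        with pytest.raises(ValueError):
            full_circular_system(CircularOrdering("ab"))


class TestPairIncidence:
    def test_trivial_split_row(self):
        theta = CircularOrdering("abcd")
        ss = full_circular_system(theta)
        m = pair_incidence(ss)
        s = make_split(theta.taxa, {"a"})
        hits = {p for p in m.pairs if m.entry(s, p)}
        assert hits == {("a", "b"), ("a", "c"), ("a", "d")}

    @pytest.mark.parametrize("n,k,seed", [(5, 6, 0), (6, 9, 1), (7, 12, 2)])
    def test_full_row_rank_for_circular_systems(self, n, k, seed):
        ss, _ = random_circular_split_system(n, k, seed)
        assert pair_incidence(ss).rank() == len(ss)

    def test_full_system_matrix_is_square_invertible(self):
        theta = CircularOrdering("abcd")
        m = pair_incidence(full_circular_system(theta))
        mat = sympy.Matrix([m.row(s) for s in m.splits])
        assert mat.shape == (6, 6)
        assert mat.det() != 0


class TestDistances:
    def test_example_pairwise_distance(self, unrooted_example):
        d = distances(unrooted_example)
        # oracle: enumerate separating splits
        expected = sum(
            w for s, w in unrooted_example.items() if s.separates("a", "e")
        )
        assert d.get("a", "e") == expected == 16

    def test_zero_weighting_gives_zero_distances(self):
        ss, _ = random_circular_split_system(5, 5, 0)
        from phylodiv import SplitWeighting

        lam = SplitWeighting(ss, {s: 0 for s in ss})
        d = distances(lam)
        assert all(v == 0 for _, v in d.items())

    @pytest.mark.parametrize("seed", range(4))
    def test_distinct_weightings_give_distinct_distances(self, seed):
        ss, _ = random_circular_split_system(5, 7, seed)
        lam1 = random_split_weighting(ss, seed)
        lam2 = random_split_weighting(ss, seed + 1000)
        assert lam1 != lam2
        d1, d2 = distances(lam1), distances(lam2)
        assert any(d1.get(*p) != d2.get(*p) for p in ss.taxa.pairs())


class TestFullRightInverse:
    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_construction_validates_m_r_identity(self, n):
        theta = CircularOrdering(taxon_labels(n))
        full_right_inverse(theta)  # raises if M·R != I

    @pytest.mark.parametrize("n", [4, 5])
    def test_equals_exact_matrix_inversion(self, n):
        theta = CircularOrdering(taxon_labels(n))
        ss = full_circular_system(theta)
        r = full_right_inverse(theta)
        oracle = sympy_right_inverse(ss)
        for p in ss.taxa.pairs():
            for s in ss:
                assert r.entry(p, s) == oracle.entry(p, s)

    def test_columns_are_sparse_half_integers(self):
        theta = CircularOrdering("abcde")
        r = full_right_inverse(theta)
        for s in r.splits:
            col = [r.entry(p, s) for p in r.pairs]
            nonzero = [v for v in col if v != 0]
            assert len(nonzero) <= 4
            assert all(abs(v) == F(1, 2) for v in nonzero)

    def test_bad_inverse_is_rejected(self):
        theta = CircularOrdering("abcd")
        ss = full_circular_system(theta)
        with pytest.raises(ValueError):
            RightInverse(ss, {(("a", "b"), ss.ordered[0]): F(1, 2)})


class TestPsiR:
    def test_closed_form_gamma_cases(self):
        theta = CircularOrdering("abcde")
        s_single = make_split(theta.taxa, {"b"})
        s_pair = make_split(theta.taxa, {"b", "c"})
        assert full_gamma_entry(theta, s_single, "b") == F(1, 2)  # singleton part
        assert full_gamma_entry(theta, s_pair, "b") == F(1, 4)    # endpoint of {b,c}
        assert full_gamma_entry(theta, s_pair, "e") == F(0)       # interior of the cyclic part {d,e,a}
        assert full_gamma_entry(theta, s_pair, "d") == F(1, 4)    # endpoint of {d,e,a}

    def test_closed_form_rejects_non_interval_splits(self):
        theta = CircularOrdering("abcde")
        s = make_split(theta.taxa, {"a", "c"})
        with pytest.raises(ValueError):
            full_gamma_entry(theta, s, "a")

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_closed_form_matches_right_inverse_construction(self, n):
        theta = CircularOrdering(taxon_labels(n))
        ss = full_circular_system(theta)
        r = full_right_inverse(theta)
        assert psi_r_matrix(ss, r) == full_gamma_matrix(theta)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_row_sums_are_one(self, n):
        theta = CircularOrdering(taxon_labels(n))
        gamma = full_gamma_matrix(theta)
        assert all(gamma.row_sum(s) == 1 for s in gamma.rows)

    def test_double_sum_equals_matrix_route(self):
        theta = CircularOrdering("abcde")
        ss = full_circular_system(theta)
        r = full_right_inverse(theta)
        lam = random_split_weighting(ss, 5)
        assert psi_r(lam, r) == psi_r_matrix(ss, r).apply(lam)

    @pytest.mark.parametrize("seed", range(4))
    def test_complete_for_any_weighting(self, seed):
        theta = CircularOrdering(taxon_labels(5))
        ss = full_circular_system(theta)
        r = full_right_inverse(theta)
        lam = random_split_weighting(ss, seed)
        assert psi_r(lam, r).total() == lam.total()

    def test_single_weighted_split_reads_off_a_gamma_row(self):
        theta = CircularOrdering("abcd")
        ss = full_circular_system(theta)
        r = full_right_inverse(theta)
        s0 = make_split(theta.taxa, {"a"})
        from phylodiv import SplitWeighting

        lam = SplitWeighting(ss, {s: (F(3) if s == s0 else F(0)) for s in ss})
        gamma = full_gamma_matrix(theta)
        vec = psi_r(lam, r)
        assert vec.as_tuple() == tuple(3 * v for v in gamma.row(s0))


class TestRestrictedPsi:
    def test_full_system_restriction_is_identity(self):
        theta = CircularOrdering("abcde")
        ss = full_circular_system(theta)
        gamma = full_gamma_matrix(theta)
        assert restricted_psi(ss, theta, "psi1") == gamma
        assert restricted_psi(ss, theta, "psi2") == gamma

    def test_quartet_example_r0_and_rhalf(self):
        """On the 5-split compatible quartet system the row restriction
        and column restriction give different complete indices: the
        non-trivial split row agrees (all 1/4) while the trivial rows
        differ in how the off-part mass is placed."""
        theta = CircularOrdering("abcd")
        from phylodiv import make_split_system

        ss = make_split_system(
            "abcd", [{"a"}, {"b"}, {"c"}, {"d"}, {"a", "b"}]
        )
        g1 = restricted_psi(ss, theta, "psi1")
        g2 = restricted_psi(ss, theta, "psi2")
        assert g1 != g2
        for g in (g1, g2):
            assert all(g.row_sum(s) == 1 for s in g.rows)
        s_ab = make_split(theta.taxa, {"a", "b"})
        assert g1.row(s_ab) == (F(1, 4), F(1, 4), F(1, 4), F(1, 4))
        assert g2.row(s_ab) == (F(1, 4), F(1, 4), F(1, 4), F(1, 4))
        # psi1 row of a|bcd: 1/2 on a, 1/4 on the cyclic neighbours b, d
        s_a = make_split(theta.taxa, {"a"})
        assert g1.row(s_a) == (F(1, 2), F(1, 4), F(0), F(1, 4))

    @pytest.mark.parametrize("n,k,seed", [(5, 6, 0), (6, 8, 1), (6, 10, 2)])
    def test_column_restriction_stays_a_right_inverse(self, n, k, seed):
        ss, theta = random_circular_split_system(n, k, seed)
        r_sub = full_right_inverse(theta).restrict_columns(ss)  # validates M·R'=I
        gamma = psi_r_matrix(ss, r_sub)
        assert all(gamma.row_sum(s) == 1 for s in gamma.rows)

    def test_non_circular_ordering_rejected(self):
        from phylodiv import make_split_system

        ss = make_split_system("abcd", [{"a", "c"}])
        with pytest.raises(ValueError):
            restricted_psi(ss, CircularOrdering("abcd"), "psi1")
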