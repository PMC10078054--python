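"""Unit and property tests for the shared statistical primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bh_step_up, fisher_p_enumeration, rank_sum_p_enumeration
from fipkit.core_stats import (
    ContingencyTable2xN,
    bh_adjust,
    diversity,
    fisher_exact,
    rank_sum_greater,
)


class TestRankSum:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([5], [1], 0.5),  # 2 orderings, observed is the larger
            ([3, 4, 5], [1, 2], 0.1),  # 1 of C(5,2)=10 rank assignments
        ],
    )
    def test_exact_enumeration_examples(self, x, y, expected):
        res = rank_sum_greater(x, y)
        assert res.method == "exact-enumeration"
        assert res.p == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_greater([], [1.0])

    def test_normal_approximation_close_to_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            exact = rank_sum_greater(x, y, exact_max_n=12)
            approx = rank_sum_greater(x, y, exact_max_n=0)
            assert exact.method == "exact-enumeration"
            assert approx.method == "normal-approx"
            assert abs(exact.p - approx.p) < 0.01

    def test_handles_ties_with_midranks(self):
        res = rank_sum_greater([2, 2, 3], [1, 2], exact_max_n=12)
        oracle = rank_sum_p_enumeration([2, 2, 3], [1, 2])
        assert res.p == pytest.approx(oracle)

    def test_one_sided_tails_overlap(self):
        # tie-free data: the two one-sided exact tails share the observed
        # value, so their p-values sum to at least 1
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.permutation(20)[:4].astype(float)
            y = rng.permutation(30)[20:25].astype(float) + 0.5
            p_xy = rank_sum_greater(x, y).p
            p_yx = rank_sum_greater(y, x).p
            assert p_xy + p_yx >= 1.0 - 1e-12


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.2], [0.2]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    @settings(derandomize=True, max_examples=50)
    def test_matches_definition_and_permutation_equivariant(self, p, rnd):
        adj = bh_adjust(p)
        assert adj == pytest.approx(bh_step_up(p))
        assert all(a >= r - 1e-12 for a, r in zip(adj, p))
        assert all(a <= 1.0 + 1e-12 for a in adj)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        adj_perm = bh_adjust([p[i] for i in perm])
        assert adj_perm == pytest.approx([adj[i] for i in perm])


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[1, 1], [1, 1]], 1.0),
            ([[2, 0], [0, 2]], 1 / 3),  # hypergeometric over a in {0,1,2}
        ],
    )
    def test_examples(self, table, expected):
        assert fisher_exact(table).p == pytest.approx(expected)

    def test_matches_scipy_on_2x2(self):
        from scipy.stats import fisher_exact as scipy_fisher

        rng = np.random.default_rng(3)
        for _ in range(20):
            tab = rng.integers(0, 15, size=(2, 2))
            if tab.sum(axis=1).min() == 0:
                continue
            ours = fisher_exact(tab.tolist()).p
            theirs = scipy_fisher(tab, alternative="two-sided")[1]
            assert ours == pytest.approx(theirs, rel=1e-9)

    def test_degenerate_zero_row_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [1, 2]])

    def test_monte_carlo_converges_to_exact(self):
        table = [[8, 3, 5], [2, 9, 4]]
        exact = fisher_exact(table)
        mc = fisher_exact(table, max_tables=1, seed=11, n_replicates=100_000)
        assert exact.method == "exact-enumeration"
        assert mc.method == "monte-carlo"
        se = math.sqrt(exact.p * (1 - exact.p) / 100_000)
        assert abs(mc.p - exact.p) <= 3 * se + 2e-5

    def test_monte_carlo_deterministic_per_seed(self):
        table = [[5, 1, 4], [2, 6, 3]]
        a = fisher_exact(table, max_tables=1, seed=5, n_replicates=2_000)
        b = fisher_exact(table, max_tables=1, seed=5, n_replicates=2_000)
        assert a.p == b.p

    def test_monte_carlo_requires_seed(self):
        with pytest.raises(ValueError):
            fisher_exact([[5, 1], [2, 6]], max_tables=1)

    def test_2x3_matches_brute_force(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            tab = rng.integers(0, 5, size=(2, 3))
            if tab.sum(axis=1).min() == 0:
                continue
            assert fisher_exact(tab.tolist()).p == pytest.approx(
                fisher_p_enumeration(tab), rel=1e-9
            )


class TestDiversity:
    def test_uniform_closed_forms(self):
        res = diversity([1, 1, 1, 1])
        assert res.shannon == pytest.approx(math.log(4))
        assert res.inverse_simpson == pytest.approx(4.0)

    def test_single_category(self):
        res = diversity([7])
        assert res.shannon == pytest.approx(0.0)
        assert res.inverse_simpson == pytest.approx(1.0)
        assert res.chao1 == pytest.approx(1.0)

    def test_chao1_formula(self):
        # S_obs=5 with two singletons, one doubleton: 5 + 4/2 = 7
        res = diversity([1, 1, 2, 10, 20])
        assert res.chao1 == pytest.approx(7.0)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            diversity([3, 0, 1])

    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=20))
    @settings(derandomize=True, max_examples=50)
    def test_shannon_and_simpson_scale_invariant(self, counts):
        base = diversity(counts)
        scaled = diversity([c * 3 for c in counts])
        assert scaled.shannon == pytest.approx(base.shannon)
        assert scaled.inverse_simpson == pytest.approx(base.inverse_simpson)
        assert base.chao1 >= len(counts)

    def test_table_validation(self):
        with pytest.raises(ValueError):
            ContingencyTable2xN(((1,), (2,)))  # n < 2
        with pytest.raises(ValueError):
            ContingencyTable2xN(((1, -1), (2, 3)))
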