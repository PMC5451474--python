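"""Exact conditional tag-count test against independent oracles.

The oracle evaluates the conditional pmf with exact rational arithmetic
(Fractions) and sums it directly, fully independent of the incomplete-beta
route used by the implementation.
"""
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import nbinom, rankdata

from mirnatime.containers import CountMatrix
from mirnatime.de_test import (GLOBAL_RULE, PAIRWISE_RULE, PairedCounts,
                               SignificanceCriteria, ac_pointmass, ac_pvalue,
                               ac_tails, adjust_fdr, log2_fold_change)
from mirnatime.de_test import test_matrix as run_test_matrix


def ac_oracle(x: int, y: int, ratio: Fraction):
    """Direct rational summation of the conditional pmf; returns (C, D, p)."""
    def pmf(k: int) -> Fraction:
        return ratio**k * math.comb(x + k, k) / (1 + ratio) ** (x + k + 1)

    c = sum(pmf(k) for k in range(y + 1))
    d = 1 - sum(pmf(k) for k in range(y))
    p = min(Fraction(1), 2 * min(c, d))
    return float(c), float(d), float(p)


class TestPointmass:
    def test_zero_counts_equal_libraries(self):
        assert ac_pointmass(0, 0, 1e6, 1e6) == pytest.approx(0.5, abs=1e-12)

    def test_geometric_closed_form_x0(self):
        # x = 0, N1 = N2: p(y) = 2^-(y+1)
        for y in range(20):
            assert ac_pointmass(0, y, 5e5, 5e5) == pytest.approx(
                2.0 ** -(y + 1), rel=1e-12)

    def test_factorial_evaluation(self):
        # x=5, y=15, equal totals: C(20,15) * 2^-21
        expected = math.comb(20, 15) * 2.0**-21
        assert ac_pointmass(5, 15, 1e6, 1e6) == pytest.approx(expected, rel=1e-12)

    def test_no_overflow_at_large_counts(self):
        p = ac_pointmass(10_000_000, 10_000_000, 1e7, 1e7)
        assert 0.0 < p < 1.0 and np.isfinite(p)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ac_pointmass(-1, 0, 1e6, 1e6)
        with pytest.raises(ValueError):
            PairedCounts(1, 1, 0, 1e6)


class TestTails:
    def test_zero_zero_equal_libraries(self):
        c, d = ac_tails(0, 0, 1e6, 1e6)
        assert c == pytest.approx(0.5, abs=1e-12)
        assert d == pytest.approx(1.0, abs=1e-12)

    def test_partition_identity_random(self, rng):
        x = rng.integers(0, 5000, 300)
        y = rng.integers(0, 5000, 300)
        c, d = ac_tails(x, y, 1.3e6, 0.8e6)
        pm = ac_pointmass(x, y, 1.3e6, 0.8e6)
        np.testing.assert_allclose(c + d - pm, 1.0, atol=1e-10)

    def test_lower_tail_is_negative_binomial_cdf(self):
        # C = P(Y <= y | x) with Y ~ NB(size x+1, success prob N1/(N1+N2))
        for r in (0.5, 1.0, 2.0):
            n1 = 1e6
            n2 = r * n1
            x, y = np.meshgrid(np.arange(31), np.arange(31))
            c, _ = ac_tails(x.ravel(), y.ravel(), n1, n2)
            ref = nbinom.cdf(y.ravel(), x.ravel() + 1, n1 / (n1 + n2))
            np.testing.assert_allclose(c, ref, atol=1e-12)


class TestPvalue:
    def test_zero_zero_equal_libraries_is_one(self):
        assert ac_pvalue(0, 0, 1e6, 1e6) == 1.0

    @pytest.mark.parametrize("x,y,expect_small", [(10, 10, False), (5, 40, True)])
    def test_matches_direct_summation(self, x, y, expect_small):
        p = ac_pvalue(x, y, 1e6, 1e6)
        _, _, p_ref = ac_oracle(x, y, Fraction(1))
        assert p == pytest.approx(p_ref, abs=1e-10)
        if expect_small:
            assert p < 1e-5
        else:
            assert p > 0.9

    def test_exchange_symmetry_up_to_point_mass(self):
        # Conditioning on x versus on y gives the same two-sided p up to the
        # discreteness of the conditional distribution: the difference is
        # bounded by twice the larger point mass (exact symmetry is
        # impossible for a doubled conditional tail) and vanishes with depth.
        x, y = np.meshgrid(np.arange(31), np.arange(31))
        xr, yr = x.ravel(), y.ravel()
        for n1, n2 in ((1e6, 5e5), (1e6, 1e6), (1e6, 2e6)):
            a = ac_pvalue(xr, yr, n1, n2)
            b = ac_pvalue(yr, xr, n2, n1)
            bound = 2 * np.maximum(ac_pointmass(xr, yr, n1, n2),
                                   ac_pointmass(yr, xr, n2, n1))
            assert (np.abs(a - b) <= bound + 1e-12).all()
        big = np.arange(2000, 2101)
        a = ac_pvalue(big, big[::-1], 1e6, 7e5)
        b = ac_pvalue(big[::-1], big, 7e5, 1e6)
        np.testing.assert_allclose(a, b, atol=2e-2)


class TestLog2FoldChange:
    def test_equal_counts_equal_libraries_zero(self):
        assert log2_fold_change(7, 7, 1e6, 1e6) == pytest.approx(0.0, abs=1e-12)

    def test_four_fold_on_tpm_scale(self):
        # TPM 100 vs 400 at equal depth, vanishing pseudocount
        assert log2_fold_change(100, 400, 1e6, 1e6, pseudo=1e-9) == pytest.approx(
            2.0, abs=1e-6)

    def test_zero_count_with_half_pseudocount(self):
        assert log2_fold_change(0, 10, 1e6, 1e6, pseudo=0.5) == pytest.approx(
            np.log2(21.0), rel=1e-12)


def fdr_literal_oracle(p):
    m = len(p)
    ranks = rankdata(p, method="max")
    return np.minimum(1.0, np.asarray(p) * m / ranks)


def fdr_stepup_oracle(p):
    """Brute-force step-up: adjusted_i = min over j with p_j >= p_i of literal_j."""
    p = np.asarray(p)
    literal = fdr_literal_oracle(p)
    return np.array([literal[p >= pi].min() for pi in p])


class TestAdjustFdr:
    def test_single_pvalue(self):
        np.testing.assert_allclose(adjust_fdr([0.04]), [0.04])

    def test_literal_arithmetic(self):
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03], "literal"),
                                   [0.03, 0.03, 0.03])

    def test_monotone_stepup_example(self):
        np.testing.assert_allclose(adjust_fdr([0.005, 0.009, 0.05, 0.9]),
                                   [0.018, 0.018, 0.2 / 3, 0.9], atol=1e-12)

    def test_empty_input(self):
        assert adjust_fdr([]).size == 0

    @pytest.mark.parametrize("mode,oracle", [("literal", fdr_literal_oracle),
                                             ("monotone", fdr_stepup_oracle)])
    def test_matches_bruteforce_oracle(self, mode, oracle, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            p[rng.uniform(size=p.size) < 0.2] = 0.5  # force ties
            np.testing.assert_allclose(adjust_fdr(p, mode), oracle(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_order_invariance_and_monotonicity(self, pvals):
        p = np.array(pvals)
        adj = adjust_fdr(p)
        perm = np.argsort(p)[::-1]
        np.testing.assert_allclose(adjust_fdr(p[perm]), adj[perm], atol=1e-12)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])


class TestTestMatrix:
    def test_all_zero_row_not_flagged(self):
        counts = CountMatrix(pd.DataFrame(
            {"LR_35E": [0, 100], "LT_35E": [0, 100]}, index=["zero", "busy"]))
        res = run_test_matrix(counts, [("LT_35E", "LR_35E")], PAIRWISE_RULE)
        zero = res[res["mirna_id"] == "zero"].iloc[0]
        assert zero["p"] == 1.0 and not zero["significant"]

    def test_self_comparison_flags_nothing(self, small_counts):
        res = run_test_matrix(small_counts, [("LR_35E", "LR_35E")], PAIRWISE_RULE)
        assert not res["significant"].any()
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)

    def test_unknown_library_label(self, small_counts):
        with pytest.raises(KeyError, match="nonsense"):
            run_test_matrix(small_counts, [("nonsense", "LR_35E")])

    def test_orientation_up_means_higher_in_second_library(self):
        counts = CountMatrix(pd.DataFrame(
            {"a": [10, 400], "b": [400, 10]}, index=["m1", "m2"]))
        res = run_test_matrix(counts, [("a", "b")], PAIRWISE_RULE)
        assert res.set_index("mirna_id").loc["m1", "direction"] == "up"
        assert res.set_index("mirna_id").loc["m2", "direction"] == "down"

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            SignificanceCriteria("bad", p_max=-1, min_abs_log2fc=0.5)
        assert GLOBAL_RULE.min_fold_change == pytest.approx(2**0.5)
        assert PAIRWISE_RULE.min_fold_change == pytest.approx(2.0)
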