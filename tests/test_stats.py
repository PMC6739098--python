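"""Rank statistics, multiplicity control and clustering summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcmlink.stats import (
    bh_adjust,
    cluster_scores,
    kendall_tau_b,
    kendall_tau_b_many,
    ols_summary,
    score_similarity,
    selection_overlap,
)


def brute_force_tau_b(x, y):
    """O(n^2) pair-counting oracle straight from the definition."""
    n = len(x)
    s = 0
    for i, j in itertools.combinations(range(n), 2):
        s += np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
    n0 = n * (n - 1) / 2

    def tie_pairs(v):
        _, c = np.unique(v, return_counts=True)
        return float((c * (c - 1) / 2).sum())

    denom = math.sqrt((n0 - tie_pairs(x)) * (n0 - tie_pairs(y)))
    return s / denom


class TestKendallTauB:
    def test_perfect_concordance_and_reversal(self):
        assert kendall_tau_b([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
        assert kendall_tau_b([1, 2, 3], [30, 20, 10])[0] == pytest.approx(-1.0)

    def test_tied_example(self):
        tau, _ = kendall_tau_b([1, 2, 2, 3], [1, 2, 3, 3])
        assert tau == pytest.approx(0.8)

    def test_all_tied_is_undefined_not_zero(self):
        tau, p = kendall_tau_b([1, 1, 1], [1, 2, 3])
        assert math.isnan(tau) and math.isnan(p)

    def test_brute_force_oracle_many_draws(self, rng):
        for _ in range(500):
            n = rng.integers(4, 12)
            x = rng.integers(0, 5, n).astype(float)  # heavy ties
            y = rng.integers(0, 5, n).astype(float)
            if np.unique(x).size == 1 or np.unique(y).size == 1:
                continue
            tau, _ = kendall_tau_b(x, y)
            assert tau == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)

    def test_matches_scipy_with_ties(self, rng):
        from scipy.stats import kendalltau

        x = rng.integers(0, 8, 40).astype(float)
        y = x + rng.integers(-2, 3, 40)
        tau, p = kendall_tau_b(x, y)
        ref = kendalltau(x, y)  # normal approximation is used when ties exist
        assert tau == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_symmetry(self, rng):
        x = rng.standard_normal(15)
        y = rng.standard_normal(15)
        assert kendall_tau_b(x, y)[0] == pytest.approx(kendall_tau_b(y, x)[0])

    def test_exact_permutation_p_small_n(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.0, 2.0, 3.0, 5.0, 4.0]
        _, p = kendall_tau_b(x, y, method="exact")
        assert 0 < p < 1
        with pytest.raises(ValueError):
            kendall_tau_b(np.arange(9.0), np.arange(9.0), method="exact")

    def test_vectorized_matches_scalar(self, rng):
        x = rng.standard_normal(12)
        Y = rng.standard_normal((12, 6))
        Y[:, 3] = np.round(Y[:, 3])  # introduce ties in one column
        Y[:, 5] = 2.0  # constant -> undefined
        taus, ps = kendall_tau_b_many(x, Y)
        for k in range(5):
            tau_ref, p_ref = kendall_tau_b(x, Y[:, k])
            assert taus[k] == pytest.approx(tau_ref, abs=1e-12)
            assert ps[k] == pytest.approx(p_ref, rel=1e-9)
        assert math.isnan(taus[5])


class TestBhAdjust:
    def test_worked_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_output_at_least_input_and_capped(self, rng):
        p = rng.uniform(0, 1, 50)
        out = bh_adjust(p)
        assert (out >= p - 1e-15).all() and (out <= 1.0).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 40)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(0, 1, 20)
        perm = rng.permutation(20)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_nan_passthrough_and_bounds(self):
        out = bh_adjust([0.01, np.nan, 0.5])
        assert math.isnan(out[1]) and not math.isnan(out[0])
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestOls:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = ols_summary(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0) and res.adjusted_r2 == pytest.approx(1.0)

    def test_adjusted_r2_formula(self, rng):
        x = rng.standard_normal(12)
        y = x + rng.standard_normal(12)
        res = ols_summary(x, y)
        assert res.adjusted_r2 == pytest.approx(1 - (1 - res.r2) * 11 / 10)

    def test_normal_equations_oracle(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        res = ols_summary(x, y)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(y.mean() - slope * x.mean(), abs=1e-10)

    def test_zero_variance_x(self):
        with pytest.raises(ValueError):
            ols_summary(np.ones(5), np.arange(5.0))


class TestScoreSimilarity:
    def test_identical_and_negated(self):
        a = pd.Series([0.1, 0.5, 0.9], index=list("abc"))
        assert score_similarity(a, a)[0] == pytest.approx(1.0)
        assert score_similarity(a, -a + 1.0)[0] == pytest.approx(-1.0)

    def test_definition_oracle_on_common_taxa(self, rng):
        a = pd.Series(rng.uniform(0, 1, 8), index=[f"t{i}" for i in range(8)])
        b = pd.Series(rng.uniform(0, 1, 8), index=[f"t{i}" for i in range(2, 10)])
        r, _ = score_similarity(a, b)
        common = a.index.intersection(b.index)
        av, bv = a[common].to_numpy(), b[common].to_numpy()
        ref = np.mean((av - av.mean()) * (bv - bv.mean())) / (av.std() * bv.std())
        assert r == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_flagged(self):
        a = pd.Series([0.5, 0.5, 0.5], index=list("abc"))
        b = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        r, p = score_similarity(a, b)
        assert math.isnan(r)


class TestClusterScores:
    def test_identical_rows_merge_at_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]], index=list("abc"))
        order, newick, Z = cluster_scores(df)
        assert Z[0, 2] == pytest.approx(0.0)  # first merge at height 0
        assert newick.endswith(";") and "a" in newick

    def test_outlier_joins_last(self):
        df = pd.DataFrame(
            [[0.0, 0.0], [0.1, 0.0], [10.0, 10.0]], index=["a", "b", "out"]
        )
        order, _, Z = cluster_scores(df)
        # the final merge includes the outlier singleton
        assert Z[-1, 3] == 3  # all leaves united last
        assert order.index("out") in (0, 2)  # outlier at one end of the leaf order

    def test_merge_heights_nondecreasing(self, rng):
        df = pd.DataFrame(rng.uniform(0, 1, (12, 4)))
        _, _, Z = cluster_scores(df)
        assert (np.diff(Z[:, 2]) >= -1e-12).all()


class TestSelectionOverlap:
    def test_identical_full_overlap(self):
        out = selection_overlap({"A": {"x", "y"}, "B": {"x", "y"}})
        row = out[(out.system_a == "A") & (out.system_b == "B")].iloc[0]
        assert row.n_overlap == 2 and row.pct_of_a == pytest.approx(100.0)

    def test_disjoint_zero(self):
        out = selection_overlap({"A": {"x"}, "B": {"y"}})
        row = out[(out.system_a == "A") & (out.system_b == "B")].iloc[0]
        assert row.n_overlap == 0 and row.pct_of_a == 0.0

    def test_empty_selection_undefined(self):
        out = selection_overlap({"A": set(), "B": {"y"}})
        row = out[(out.system_a == "A") & (out.system_b == "B")].iloc[0]
        assert math.isnan(row.pct_of_a)


@settings(max_examples=100, deadline=None)
@given(
    st.lists(st.integers(0, 4), min_size=4, max_size=10),
    st.integers(0, 2**31 - 1),
)
def test_tau_b_property_vs_oracle(xs, seed):
    """tau-b equals the pair-counting oracle for arbitrary tied integer data."""
    rng = np.random.default_rng(seed)
    x = np.array(xs, dtype=float)
    y = rng.integers(0, 4, len(x)).astype(float)
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return
    tau, _ = kendall_tau_b(x, y)
    assert tau == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)
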