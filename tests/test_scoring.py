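"""Fractional ranks, deR scoring, and the group-level statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from teadscore import (DeRActivity, ExpressionMatrix, ScoringError, Signature,
                       UsageError, compare_groups, der_score_matrix,
                       der_score_sample, fractional_ranks, group_summary,
                       rank_cohorts)


class TestFractionalRanks:
    def test_distinct_values(self):
        fr = fractional_ranks(pd.Series({"D": 1.0, "C": 2.0, "B": 3.0, "A": 5.0}))
        assert fr.to_dict() == {"D": 0.25, "C": 0.5, "B": 0.75, "A": 1.0}

    def test_ties_get_mean_integer_rank(self):
        fr = fractional_ranks(pd.Series({"X": 5.0, "Y": 5.0, "Z": 2.0}))
        assert fr["Z"] == pytest.approx(1 / 3)
        assert fr["X"] == fr["Y"] == pytest.approx(2.5 / 3)

    def test_all_equal(self):
        fr = fractional_ranks(pd.Series([7.0] * 4))
        assert np.allclose(fr, 0.625)  # mean of ranks 1..4, / 4

    def test_mean_rank_closed_form(self, rng):
        for n in (2, 5, 17):
            fr = fractional_ranks(pd.Series(rng.normal(size=n)))
            assert fr.mean() == pytest.approx((n + 1) / (2 * n))
            assert fr.max() <= 1.0 and fr.min() > 0.0

    def test_missing_dropped_and_too_few_rejected(self):
        fr = fractional_ranks(pd.Series({"A": 1.0, "B": np.nan, "C": 3.0}))
        assert set(fr.index) == {"A", "C"}
        with pytest.raises(ScoringError):
            fractional_ranks(pd.Series({"A": 1.0, "B": np.nan}))


SIG = Signature(frozenset({"A", "B"}), frozenset({"C", "D"}))


class TestDerScoreSample:
    def test_perfect_separation_hits_upper_bound(self):
        fr = fractional_ranks(pd.Series({"A": 5.0, "B": 3.0, "C": 2.0, "D": 1.0}))
        rp, rn, der, n_pos, n_neg = der_score_sample(fr, SIG)
        assert (rp, rn, der) == (0.875, 0.375, 0.5)
        assert (n_pos, n_neg) == (2, 2)

    def test_interleaved(self):
        fr = fractional_ranks(pd.Series({"A": 1.0, "B": 3.0, "C": 2.0, "D": 4.0}))
        rp, rn, der, *_ = der_score_sample(fr, SIG)
        assert (rp, rn, der) == (0.5, 0.75, -0.25)

    def test_constant_sample_scores_zero(self):
        fr = fractional_ranks(pd.Series({"A": 2.0, "B": 2.0, "C": 2.0, "D": 2.0}))
        assert der_score_sample(fr, SIG)[2] == 0.0

    def test_direction_with_no_measured_member_errors(self):
        fr = fractional_ranks(pd.Series({"A": 1.0, "B": 2.0}))
        with pytest.raises(ScoringError, match="negative"):
            der_score_sample(fr, SIG)


class TestDerScoreMatrix:
    def _matrix(self, rows, samples):
        return ExpressionMatrix(pd.DataFrame(
            rows, index=samples, columns=["A", "B", "C", "D"]))

    def test_two_sample_matrix(self):
        mat = self._matrix([[5.0, 3.0, 2.0, 1.0], [1.0, 2.0, 3.0, 5.0]],
                           ["s1", "s2"])
        scores = der_score_matrix(mat, SIG)
        assert scores.loc["s1", "deR"] == 0.5
        assert scores.loc["s2", "deR"] == -0.5

    def test_monotone_transform_invariance(self, rng):
        vals = rng.normal(size=(5, 4))
        base = der_score_matrix(self._matrix(vals, list("vwxyz")), SIG)
        for f in (np.exp, lambda x: 3 * x + 7, lambda x: x ** 3):
            transformed = der_score_matrix(self._matrix(f(vals), list("vwxyz")), SIG)
            assert np.allclose(base["deR"], transformed["deR"], atol=1e-12)

    def test_gene_order_invariance(self, rng):
        vals = pd.DataFrame(rng.normal(size=(3, 4)), index=list("abc"),
                            columns=["A", "B", "C", "D"])
        base = der_score_matrix(ExpressionMatrix(vals), SIG)
        shuffled = der_score_matrix(
            ExpressionMatrix(vals[["C", "A", "D", "B"]]), SIG)
        assert np.allclose(base["deR"], shuffled["deR"])

    def test_missing_values_dropped_per_sample(self, der_oracle):
        vals = pd.DataFrame(
            [[5.0, np.nan, 2.0, 1.0], [1.0, 2.0, 3.0, 5.0]],
            index=["s1", "s2"], columns=["A", "B", "C", "D"])
        scores = der_score_matrix(ExpressionMatrix(vals), SIG)
        assert scores.loc["s1", "n_pos_used"] == 1
        _, _, expected = der_oracle(vals.loc["s1"].to_dict(), ["A", "B"], ["C", "D"])
        assert scores.loc["s1", "deR"] == pytest.approx(expected, abs=1e-12)

    def test_unscorable_sample_reported_not_fatal(self):
        vals = pd.DataFrame(
            [[5.0, 3.0, np.nan, np.nan], [1.0, 2.0, 3.0, 5.0]],
            index=["s1", "s2"], columns=["A", "B", "C", "D"])
        res = DeRActivity(ExpressionMatrix(vals), SIG).fit()
        assert np.isnan(res.scores.loc["s1", "deR"])
        assert "s1" in res.errors
        assert res.scores.loc["s2", "deR"] == -0.5

    def test_low_coverage_warns(self, rng):
        big_sig = Signature(frozenset({"A", "P1", "P2"}), frozenset({"C", "D"}))
        vals = pd.DataFrame(rng.normal(size=(3, 4)), index=list("abc"),
                            columns=["A", "B", "C", "D"])
        with pytest.warns(UserWarning, match="positive effectors"):
            der_score_matrix(ExpressionMatrix(vals), big_sig)

    def test_all_genes_universe_uses_full_ranking(self, rng):
        # with nulls present, effectors-only and all-genes ranks differ
        vals = pd.DataFrame(
            [[5.0, 3.0, 2.0, 1.0, 10.0, 0.5]], index=["s1"],
            columns=["A", "B", "C", "D", "N1", "N2"])
        eff = der_score_matrix(ExpressionMatrix(vals), SIG, rank_universe="effectors")
        full = der_score_matrix(ExpressionMatrix(vals), SIG, rank_universe="all-genes")
        assert eff.loc["s1", "deR"] == 0.5
        # all-genes: ranks /6 -> Rp=(5/6+4/6)/2, Rn=(3/6+2/6)/2
        assert full.loc["s1", "deR"] == pytest.approx((4.5 - 2.5) / 6)


class TestCompareGroups:
    def test_exact_no_overlap_3v3(self):
        scores = pd.Series([0.4, 0.45, 0.5, -0.5, -0.45, -0.4],
                           index=list("abcdef"))
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=list("abcdef"))
        res = compare_groups(scores, labels, "A", "B")
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.1)  # 2/C(6,3) arrangements
        assert res.median_difference == pytest.approx(0.9)

    def test_identical_groups(self):
        scores = pd.Series(np.tile([0.1, 0.2, 0.3], 2), index=range(6))
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=range(6))
        res = compare_groups(scores, labels, "A", "B")
        assert res.pvalue == pytest.approx(1.0)
        assert res.median_difference == 0.0

    def test_swap_symmetry(self, rng):
        scores = pd.Series(rng.normal(size=12))
        labels = pd.Series(["A"] * 6 + ["B"] * 6)
        ab = compare_groups(scores, labels, "A", "B")
        ba = compare_groups(scores, labels, "B", "A")
        assert ab.pvalue == pytest.approx(ba.pvalue)
        assert ab.median_difference == pytest.approx(-ba.median_difference)

    def test_small_group_rejected(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0])
        labels = pd.Series(["A", "A", "B", "B"])
        with pytest.raises(UsageError, match="n >= 3"):
            compare_groups(scores, labels, "A", "B")


class TestGroupSummary:
    def test_t_interval_closed_form(self):
        scores = pd.Series([0.1, 0.2, 0.3])
        labels = pd.Series(["g"] * 3)
        summ = group_summary(scores, labels)
        row = summ.iloc[0]
        half = stats.t.ppf(0.975, 2) * 0.1 / np.sqrt(3)
        assert row["mean"] == pytest.approx(0.2)
        assert row["ci_high"] - row["mean"] == pytest.approx(half)
        assert row["ci_low"] <= row["mean"] <= row["ci_high"]

    def test_singleton_group_ci_flagged(self):
        summ = group_summary(pd.Series([0.4, 0.1, 0.2]),
                             pd.Series(["solo", "pair", "pair"]))
        solo = summ[summ["group"] == "solo"].iloc[0]
        assert np.isnan(solo["ci_low"]) and np.isnan(solo["ci_high"])
        assert solo["mean"] == 0.4

    def test_ci_width_shrinks_with_n(self, rng):
        x = rng.normal(size=400)
        small = group_summary(pd.Series(x[:20]), pd.Series(["g"] * 20)).iloc[0]
        big = group_summary(pd.Series(x), pd.Series(["g"] * 400)).iloc[0]
        assert (big["ci_high"] - big["ci_low"]) < (small["ci_high"] - small["ci_low"])

    def test_bootstrap_interval_contains_mean(self, rng):
        x = pd.Series(rng.normal(size=30))
        summ = group_summary(x, pd.Series(["g"] * 30),
                             ci_method="bootstrap", seed=1)
        row = summ.iloc[0]
        assert row["ci_low"] <= row["mean"] <= row["ci_high"]


class TestRankCohorts:
    def test_shifted_cohort_ranked_first(self, rng):
        scores = pd.Series(np.concatenate([
            rng.normal(0.2, 0.05, 40), rng.normal(0.0, 0.05, 40)]))
        labels = pd.Series(["shifted"] * 40 + ["null"] * 40)
        tab = rank_cohorts(scores, labels)
        assert tab.iloc[0]["cohort"] == "shifted"
        assert list(tab["rank"]) == [1, 2]

    def test_tie_broken_lexicographically(self):
        scores = pd.Series([0.1, 0.2, 0.2, 0.1])
        labels = pd.Series(["b", "b", "a", "a"])
        tab = rank_cohorts(scores, labels)
        assert list(tab["cohort"]) == ["a", "b"]

    def test_constant_shift_preserves_order(self, rng):
        scores = pd.Series(rng.normal(size=30))
        labels = pd.Series(rng.choice(["x", "y", "z"], size=30))
        base = rank_cohorts(scores, labels)["cohort"]
        shifted = rank_cohorts(scores + 5.0, labels)["cohort"]
        assert list(base) == list(shifted)
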