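"""Wilcoxon, Spearman, bootstrap-smoothed ROC and the cohort summary."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pgxcohort.stats import (
    DegenerateInputError,
    dichotomize_effectiveness,
    empirical_auc,
    roc_bootstrap_smoothed,
    spearman_correlation,
    summarize_cohort,
    wilcoxon_paired,
)


def all_improving_pairs(n):
    """n pairs, every follow-up strictly below baseline, untied |differences|."""
    baseline = np.full(n, 50.0)
    followup = baseline - np.arange(1, n + 1, dtype=float)
    return baseline, followup


class TestWilcoxon:
    @pytest.mark.parametrize("n", [5, 10, 46, 100])
    def test_one_signed_untied_closed_form(self, n):
        """With all differences one-signed and untied the statistic
        depends only on n: |Z| = (n(n+1)/4) / sqrt(n(n+1)(2n+1)/24)."""
        b, f = all_improving_pairs(n)
        res = wilcoxon_paired(b, f)
        expected_z = (n * (n + 1) / 4) / math.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        assert res.W_statistic == 0.0
        assert abs(res.Z) == pytest.approx(expected_z)
        assert res.effect_size_r == pytest.approx(expected_z / math.sqrt(2 * n))

    def test_printed_effect_size_convention(self):
        """46 improving pairs reproduce the 0.62 effect size under the
        total-observations convention; the pairs convention gives 0.87."""
        b, f = all_improving_pairs(46)
        res = wilcoxon_paired(b, f)
        assert abs(res.Z) == pytest.approx(540.5 / math.sqrt(8377.75))
        assert round(res.effect_size_r, 2) == 0.62
        res_pairs = wilcoxon_paired(b, f, effect_size_convention="pairs")
        assert round(res_pairs.effect_size_r, 2) == 0.87

    def test_all_zero_differences_degenerate(self):
        x = [5.0, 4.0, 3.0, 2.0, 1.0]
        with pytest.raises(DegenerateInputError):
            wilcoxon_paired(x, x)

    def test_zero_differences_dropped(self):
        b = np.array([5, 4, 3, 2, 1, 9, 8], dtype=float)
        f = b.copy()
        f[:5] -= [1, 2, 3, 4, 5]
        res = wilcoxon_paired(b, f)
        assert res.n_pairs == 5
        assert res.n_zero_dropped == 2

    def test_exact_p_matches_sign_enumeration(self):
        """Exact-mode p equals the brute-force permutation p over all
        2^6 sign assignments of the ranked |differences|."""
        d = np.array([1.5, -2.2, 3.1, 4.0, 5.5, 6.1])
        b = np.zeros(6)
        f = d.copy()
        ranks = sps.rankdata(np.abs(d))
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        count = 0
        for signs in itertools.product([1.0, -1.0], repeat=6):
            s = np.asarray(signs)
            w = min(ranks[s > 0].sum(), ranks[s < 0].sum())
            if w <= w_obs:
                count += 1
        brute_p = count / 2**6
        res = wilcoxon_paired(b, f, method="exact")
        assert res.p_value == pytest.approx(brute_p)

    def test_exact_and_approx_agree_on_rejection(self):
        """Normal-approximation and exact p agree in the alpha = 0.05
        rejection decision on at least 95% of random small-n instances."""
        rng = np.random.default_rng(42)
        agree = 0
        trials = 200
        for _ in range(trials):
            n = int(rng.integers(6, 11))
            d = rng.normal(rng.uniform(-2, 2), 1.0, size=n)
            d = np.where(d == 0, 0.1, d)
            b = np.zeros(n)
            approx = wilcoxon_paired(b, d).p_value
            exact = wilcoxon_paired(b, d, method="exact").p_value
            agree += (approx < 0.05) == (exact < 0.05)
        assert agree / trials >= 0.95

    def test_effect_size_labels(self):
        b, f = all_improving_pairs(46)
        assert wilcoxon_paired(b, f).effect_size_label == "large"


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)

    def test_perfect_inverse(self):
        assert spearman_correlation([1, 2, 3, 4], [4, 3, 2, 1]).rho == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0])
        y = np.array([3.0, 3.0, 1.0, 4.0, 2.0, 5.0, 5.0, 6.0])
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_correlation(x, y).rho == pytest.approx(oracle)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        base = spearman_correlation(x, y).rho
        assert spearman_correlation(np.exp(x), y).rho == pytest.approx(base)
        assert spearman_correlation(x, y**3).rho == pytest.approx(base)

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateInputError):
            spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])


class TestRoc:
    def test_empirical_auc_equals_mannwhitney_identity(self):
        """Empirical AUC equals U / (n1 * n0) with U counted by brute
        force over all positive-negative pairs."""
        scores = np.array([3.0, 1.0, 2.0, 8.0, 7.0, 2.5, 9.0, 0.5, 6.0, 4.0])
        labels = np.array([0, 0, 0, 1, 1, 0, 1, 0, 1, 1])
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        u = sum(
            1.0 if p > q else (0.5 if p == q else 0.0)
            for p in pos
            for q in neg
        )
        assert empirical_auc(scores, labels) == pytest.approx(u / (len(pos) * len(neg)))

    def test_perfect_separation_auc_one(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.zeros(10, int), np.ones(10, int)]
        for n_boot, seed in [(5, 0), (50, 9)]:
            assert roc_bootstrap_smoothed(scores, labels, n_boot, seed).auc == pytest.approx(1.0)

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        res = roc_bootstrap_smoothed(scores, labels, n_boot=200, seed=5)
        assert abs(res.auc - 0.5) < 0.03

    def test_reproducible_bit_identical(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=60)
        labels = (scores + rng.normal(size=60) > 0).astype(int)
        a = roc_bootstrap_smoothed(scores, labels, n_boot=50, seed=77)
        b = roc_bootstrap_smoothed(scores, labels, n_boot=50, seed=77)
        assert a == b

    def test_smoothed_converges_to_empirical(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=80)
        labels = (scores + rng.normal(size=80) > 0).astype(int)
        emp = empirical_auc(scores, labels)
        d10 = abs(roc_bootstrap_smoothed(scores, labels, 10, seed=4).auc - emp)
        d1000 = abs(roc_bootstrap_smoothed(scores, labels, 1000, seed=4).auc - emp)
        assert d1000 <= d10

    def test_mean_tpr_monotone(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        res = roc_bootstrap_smoothed(scores, labels, n_boot=20, seed=3)
        assert np.all(np.diff(res.mean_tpr) >= 0)
        assert res.auc == pytest.approx(np.trapezoid(res.mean_tpr, res.fpr_grid))

    def test_single_class_degenerate(self):
        with pytest.raises(DegenerateInputError):
            roc_bootstrap_smoothed([1.0, 2.0, 3.0], [1, 1, 1], 10, 0)


class TestDichotomize:
    def test_rule(self):
        assert dichotomize_effectiveness([9, 7, 8], 8).tolist() == [1, 0, 1]

    def test_threshold_one_labels_everything(self):
        assert dichotomize_effectiveness([1, 5, 10], 1).tolist() == [1, 1, 1]

    def test_all_negative_propagates_to_roc_error(self):
        labels = dichotomize_effectiveness([5, 6, 7, 4], 10)
        assert labels.tolist() == [0, 0, 0, 0]
        with pytest.raises(DegenerateInputError):
            roc_bootstrap_smoothed([1.0, 2.0, 3.0, 4.0], labels, 10, 0)


class TestSummary:
    def test_mean_sd_hand_arithmetic(self):
        frame = pd.DataFrame({"age": [30.0, 40.0]})
        s = summarize_cohort(frame)
        assert s.means["age"] == pytest.approx(35.0)
        assert s.sds["age"] == pytest.approx(7.0710678)

    def test_single_female_percentage(self):
        frame = pd.DataFrame({"sex": ["Female"]})
        s = summarize_cohort(frame)
        assert s.counts["sex"]["Female"] == 1
        assert s.percents["sex"]["Female"] == pytest.approx(100.0)

    def test_empty_followup_column_missing(self):
        frame = pd.DataFrame({"age": [30.0], "followup_total": [np.nan]})
        s = summarize_cohort(frame)
        assert "followup_total" not in s.means
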