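"""Evaluation statistics against closed forms and enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from habikit.stats import (
    auc,
    auc_ci,
    chi_square_test,
    dca,
    delong_test,
    eval_report,
    fleiss_kappa,
    group_location_test,
    hosmer_lemeshow,
    mcnemar_test,
    pr_auc,
    prevalence_percent,
)


class TestAuc:
    def test_perfect_ranking(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        a, lo, hi = auc_ci(scores, labels)
        assert a == 1.0
        assert hi == 1.0

    @given(seed=st.integers(0, 500))
    @settings(max_examples=40, deadline=None)
    def test_equals_mann_whitney_u(self, seed):
        """AUC is identically the normalized Mann-Whitney U statistic."""
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 40)
        scores = rng.normal(size=n).round(1)  # ties included
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
        if labels.sum() in (0, n):
            return
        u = sps.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        expected = u / (labels.sum() * (n - labels.sum()))
        assert auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_ci_covers_null_auc(self):
        """With uninformative scores the CI covers 0.5 in ~95% of runs."""
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            scores = rng.uniform(size=200)
            labels = rng.integers(0, 2, size=200)
            if labels.sum() in (0, 200):
                continue
            _, lo, hi = auc_ci(scores, labels)
            covered += lo <= 0.5 <= hi
        assert covered >= 93

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        z, p, a1, a2 = delong_test(s, s, labels)
        assert z == 0.0 and p == 1.0 and a1 == a2

    def test_variance_matches_direct_placement_covariance(self):
        """DeLong variance of one AUC equals the explicit S10/m + S01/n form."""
        rng = np.random.default_rng(3)
        scores = rng.normal(size=20)
        labels = np.array([1] * 8 + [0] * 12)
        pos, neg = scores[labels == 1], scores[labels == 0]
        # direct placement values via pair counting
        v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / len(neg) for p in pos])
        v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / len(pos) for q in neg])
        expected_auc = v10.mean()
        expected_var = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
        a, lo, hi = auc_ci(scores, labels)
        assert a == pytest.approx(expected_auc, abs=1e-12)
        se = (hi - a) / sps.norm.ppf(0.975)
        assert se ** 2 == pytest.approx(expected_var, rel=1e-9)

    def test_type_one_error_smoke(self):
        """Null rejection rate near nominal on a small batch (full check in acceptance)."""
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            base = rng.normal(size=100)
            labels = np.array([0, 1] * 50)
            sa = base + rng.normal(scale=0.5, size=100)
            sb = base + rng.normal(scale=0.5, size=100)
            _, p, *_ = delong_test(sa, sb, labels)
            rejections += p < 0.05
        assert 0.01 <= rejections / n_rep <= 0.10


class TestEvalReport:
    def test_two_by_two_arithmetic(self):
        # TP=8, FP=2, FN=2, TN=8
        labels = np.array([1] * 10 + [0] * 10)
        calls = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)
        scores = calls.astype(float)
        rep = eval_report(scores, calls, labels)
        assert rep.sensitivity == 0.8
        assert rep.specificity == 0.8
        assert rep.ppv == 0.8
        assert rep.accuracy == 0.8
        assert rep.f1 == pytest.approx(0.8)
        assert rep.precision == rep.ppv and rep.recall == rep.sensitivity

    def test_identities_hold_on_random_data(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        calls = rng.integers(0, 2, size=50)
        scores = rng.uniform(size=50)
        rep = eval_report(scores, calls, labels)
        assert rep.f1 == pytest.approx(
            2 * rep.ppv * rep.sensitivity / (rep.ppv + rep.sensitivity)
        )
        assert rep.ci_lower <= rep.auc <= rep.ci_upper


class TestMcNemar:
    def test_no_discordance(self):
        labels = np.array([0, 1, 0, 1])
        assert mcnemar_test(labels, labels, labels) == 1.0

    def test_symmetric_discordance(self):
        # b = c = 10: exact binomial, perfectly symmetric
        labels = np.zeros(20, dtype=int)
        calls_a = np.array([0] * 10 + [1] * 10)  # correct on first half
        calls_b = np.array([1] * 10 + [0] * 10)
        assert mcnemar_test(calls_a, calls_b, labels) == pytest.approx(1.0)

    def test_exact_binomial_value(self):
        # b = 9, c = 1 -> p = 2 * P(X <= 1 | Bin(10, 1/2))
        labels = np.zeros(10, dtype=int)
        calls_a = np.array([0] * 9 + [1])
        calls_b = np.array([1] * 9 + [0])
        expected = 2 * sum(sps.binom.pmf(k, 10, 0.5) for k in (0, 1))
        assert mcnemar_test(calls_a, calls_b, labels) == pytest.approx(expected)
        assert expected == pytest.approx(0.021484375)


class TestHosmerLemeshow:
    def test_calibrated_simulation_accepts(self):
        # probabilities are external (no model fit on these labels), so the
        # null is chi-square with g degrees of freedom: fitted_params=0
        accept = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            probs = rng.uniform(0.05, 0.95, size=1000)
            labels = (rng.uniform(size=1000) < probs).astype(int)
            accept += hosmer_lemeshow(probs, labels, fitted_params=0).p_value > 0.05
        assert accept >= 90

    def test_anticalibrated_rejects(self):
        rng = np.random.default_rng(5)
        probs = rng.uniform(0.05, 0.95, size=1000)
        labels = (rng.uniform(size=1000) < probs).astype(int)
        rep = hosmer_lemeshow(1 - probs, labels)
        assert rep.p_value < 0.001

    def test_bin_counts_sum_to_n(self):
        rng = np.random.default_rng(2)
        probs = rng.uniform(size=200)
        labels = rng.integers(0, 2, size=200)
        rep = hosmer_lemeshow(probs, labels)
        assert sum(b["n"] for b in rep.bin_table) == 200
        assert rep.df == len(rep.bin_table) - 2

    def test_too_few_distinct_probs_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow(np.array([0.5] * 20), np.zeros(20, dtype=int))


class TestDca:
    def test_treat_all_closed_form(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, size=100)
        pi = labels.mean()
        curve = dca(rng.uniform(size=100), labels)
        t = curve.thresholds
        np.testing.assert_allclose(curve.treat_all, pi - (1 - pi) * t / (1 - t))
        assert np.all(curve.treat_none == 0)

    def test_perfect_model_net_benefit_is_prevalence(self):
        labels = np.array([0] * 60 + [1] * 40)
        probs = labels.astype(float)
        curve = dca(probs, labels, thresholds=np.array([0.1, 0.5, 0.9]))
        np.testing.assert_allclose(curve.net_benefit, 0.4)

    def test_model_never_beats_perfect_bound(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, size=300)
        probs = np.clip(labels * 0.6 + rng.uniform(size=300) * 0.4, 0, 1)
        curve = dca(probs, labels)
        assert np.all(curve.net_benefit <= labels.mean() + 1e-12)


class TestPrAuc:
    def test_perfect_ranking(self):
        assert pr_auc([0.1, 0.9, 0.8, 0.2], [0, 1, 1, 0]) == 1.0

    def test_four_case_hand_computation(self):
        # descending-score order of labels: 1, 0, 1, 0
        scores = np.array([0.9, 0.8, 0.6, 0.3])
        labels = np.array([1, 0, 1, 0])
        # steps: recall 0->0.5 at precision 1; 0.5->1.0 at precision 2/3
        expected = 0.5 * 1.0 + 0.5 * (2 / 3)
        assert pr_auc(scores, labels) == pytest.approx(expected)

    def test_null_scores_approach_prevalence(self):
        rng = np.random.default_rng(11)
        labels = (rng.uniform(size=4000) < 0.3).astype(int)
        scores = rng.uniform(size=4000)
        assert pr_auc(scores, labels) == pytest.approx(0.3, abs=0.05)


class TestFleissKappa:
    def test_full_agreement_mixed_categories(self):
        ratings = np.array([[1, 1, 1], [2, 2, 2], [3, 3, 3], [1, 1, 1]])
        assert fleiss_kappa(ratings) == pytest.approx(1.0)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(0)
        ratings = rng.integers(1, 4, size=(300, 3))
        assert abs(fleiss_kappa(ratings)) < 0.1

    def test_hand_computed_two_by_two(self):
        ratings = np.array([[1, 1], [1, 2], [2, 2], [2, 2]])
        # direct Fleiss formula on category counts
        counts = np.array([[2, 0], [1, 1], [0, 2], [0, 2]])
        n, k = 4, 2
        p_i = ((counts ** 2).sum(axis=1) - k) / (k * (k - 1))
        p_bar = p_i.mean()
        p_j = counts.sum(axis=0) / (n * k)
        p_e = (p_j ** 2).sum()
        expected = (p_bar - p_e) / (1 - p_e)
        assert fleiss_kappa(ratings) == pytest.approx(expected)

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.ones((10, 3)))


class TestBaselineTests:
    def test_sex_by_cohort_table(self):
        _, p = chi_square_test([[169, 44, 63], [39, 8, 14]])
        assert p == pytest.approx(0.85, abs=0.005)

    def test_pn_by_cohort_table(self):
        _, p = chi_square_test([[86, 20, 23], [122, 32, 54]])
        assert p == pytest.approx(0.21, abs=0.005)

    def test_identical_row_proportions_give_p_one(self):
        _, p = chi_square_test([[10, 20, 30], [20, 40, 60]])
        assert p == pytest.approx(1.0)

    def test_group_location_parametric_vs_nonparametric(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 40)
        b = rng.normal(2, 1, 40)
        assert group_location_test([a, b], method="parametric") < 1e-6
        assert group_location_test([a, b], method="nonparametric") < 1e-6


class TestPrevalence:
    def test_training_cohort_worked_example(self):
        labels = np.array([1] * 122 + [0] * 86)
        assert prevalence_percent(labels) == 58.65
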