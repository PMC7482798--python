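import itertools

import numpy as np
import pytest
from scipy import stats as sps

from immunopet import (
    SeparationError,
    logistic_fit,
    rank_sum_test,
    roc_analysis,
    spearman_rho,
    survival_analysis,
)
from immunopet.stats import StatsError

from .oracles import brute_auc


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        r = spearman_rho([1, 2, 3, 4, 5], [2, 4, 9, 16, 30])
        assert r.statistic == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        r = spearman_rho([1, 2, 3, 4], [8, 6, 4, 2])
        assert r.statistic == pytest.approx(-1.0)

    def test_exact_p_matches_enumeration_with_ties(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 2.0, 5.0, 1.0, 7.0, 6.0]  # one tie pair
        res = spearman_rho(x, y)
        # independent oracle: enumerate all 720 permutations with scipy rho
        obs = sps.spearmanr(x, y).statistic
        count = 0
        perms = list(itertools.permutations(y))
        for p in perms:
            if abs(sps.spearmanr(x, list(p)).statistic) >= abs(obs) - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / len(perms))
        assert res.method == "exact permutation"

    def test_large_n_uses_t_approximation(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        res = spearman_rho(x, y)
        ref = sps.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_all_tied_rejected(self):
        with pytest.raises(StatsError, match="tied"):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(StatsError):
            spearman_rho([1, 2, 3], [1, 2])


class TestRankSum:
    def test_separated_triples_exact_p(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact enumeration"

    def test_identical_multisets_give_p_one(self):
        res = rank_sum_test([1, 2, 5], [1, 2, 5])
        assert res.p_value == pytest.approx(1.0)

    def test_p_decreases_with_shift(self, rng):
        base = rng.normal(size=30)
        pvals = [rank_sum_test(base, base + delta).p_value for delta in (0.3, 0.8, 1.5)]
        assert pvals[0] > pvals[1] > pvals[2]

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            rank_sum_test([], [1, 2])

    def test_type_i_error_near_nominal(self):
        # null simulations at n = 10 + 10 (normal-approximation branch)
        rng = np.random.default_rng(42)
        rejections = 0
        n_sim = 5000
        for _ in range(n_sim):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            if rank_sum_test(a, b).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07


class TestROC:
    def test_perfect_separation(self):
        res = roc_analysis([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == pytest.approx(1.0)
        assert res.sensitivity == pytest.approx(1.0)
        assert res.specificity == pytest.approx(1.0)

    def test_all_scores_equal_gives_half(self):
        res = roc_analysis([1.0] * 6, [0, 1, 0, 1, 0, 1])
        assert res.auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_all_pairs_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 21))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(brute_auc(scores, labels))

    def test_youden_cutoff_consistent_with_dichotomization(self, rng):
        scores = rng.normal(size=40)
        labels = (scores + rng.normal(scale=0.8, size=40)) > 0
        res = roc_analysis(scores, labels)
        sens = np.mean(scores[labels] > res.optimal_cutoff)
        spec = np.mean(scores[~labels] <= res.optimal_cutoff)
        assert sens == pytest.approx(res.sensitivity)
        assert spec == pytest.approx(res.specificity)

    def test_single_class_rejected(self):
        with pytest.raises(StatsError):
            roc_analysis([1, 2, 3], [1, 1, 1])

    def test_delong_ci_brackets_auc(self, rng):
        scores = rng.normal(size=60)
        labels = (scores + rng.normal(size=60)) > 0
        res = roc_analysis(scores, labels)
        lo, hi = res.ci95
        assert lo <= res.auc <= hi
        assert 0 <= lo and hi <= 1


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = [1, 0, 0, 0] * 5
        fit = logistic_fit(y, np.zeros((20, 0)))
        assert fit.loc["intercept", "coef"] == pytest.approx(np.log(1 / 3), abs=1e-6)

    def test_single_covariate_matches_grid_search(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = (rng.random(30) < 1 / (1 + np.exp(-(0.5 + 1.2 * x)))).astype(float)
        fit = logistic_fit(y, x[:, None])
        # brute-force likelihood maximization over a grid
        b0s = np.linspace(-3, 3, 241)
        b1s = np.linspace(-3, 4, 281)
        best, best_ll = None, -np.inf
        for b0 in b0s:
            eta = b0 + np.outer(b1s, x)
            ll = (y * eta - np.log1p(np.exp(eta))).sum(axis=1)
            i = np.argmax(ll)
            if ll[i] > best_ll:
                best_ll, best = ll[i], (b0, b1s[i])
        assert fit.loc["intercept", "coef"] == pytest.approx(best[0], abs=0.05)
        assert fit.loc["x0", "coef"] == pytest.approx(best[1], abs=0.05)

    def test_separable_data_raises(self):
        x = np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0, 2.5, 3.0])
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError, match="firth"):
            logistic_fit(y, x[:, None])

    def test_firth_handles_separation(self):
        x = np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0, 2.5, 3.0])
        y = (x > 0).astype(float)
        fit = logistic_fit(y, x[:, None], firth=True)
        assert np.isfinite(fit["coef"]).all()
        assert fit.loc["x0", "coef"] > 0


class TestSurvival:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        e = [1] * 10
        g = ["a"] * 5 + ["b"] * 5
        fit = survival_analysis(t, e, g)
        assert fit.logrank_p == pytest.approx(1.0)
        assert fit.hazard_ratio == pytest.approx(1.0, abs=1e-6)

    def test_logrank_matches_hand_tabulation(self):
        # group A events at {1, 2}, group B at {3, 4}, no censoring:
        # O_A = 2, E_A = 1/2 + 1/3 = 5/6, V = 1/4 + 2/9 = 17/36
        # chi2 = (2 - 5/6)^2 / (17/36) = 49/17
        fit = survival_analysis([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
        assert fit.logrank_chi2 == pytest.approx(49 / 17, rel=1e-9)

    def test_km_censoring_decrements_risk_set_only(self):
        fit = survival_analysis(
            [2, 3, 5, 2, 4, 6], [1, 0, 1, 1, 1, 1], list("aaabbb")
        )
        km_a = fit.km["a"]
        # survival unchanged at censoring time 3
        s = km_a.set_index("time")["survival"]
        assert s.loc[3.0] == pytest.approx(s.loc[2.0])
        # non-increasing, starts at 1
        for name, km in fit.km.items():
            surv = km["survival"].to_numpy()
            assert surv[0] == pytest.approx(1.0)
            assert np.all(np.diff(surv) <= 1e-12)

    def test_logrank_invariant_to_monotone_time_transform(self, rng):
        t = rng.exponential(5, size=30) + 0.1
        e = rng.integers(0, 2, size=30)
        g = np.array(["a", "b"] * 15)
        f1 = survival_analysis(t, e, g)
        f2 = survival_analysis(np.exp(t / 10), e, g)
        assert f1.logrank_chi2 == pytest.approx(f2.logrank_chi2, rel=1e-9)

    def test_zero_event_group_flagged(self):
        fit = survival_analysis([1, 2, 3, 4], [0, 0, 1, 1], ["a", "a", "b", "b"])
        assert not fit.hr_defined
        assert np.isnan(fit.hazard_ratio)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(StatsError):
            survival_analysis([0, 1], [1, 1], ["a", "b"])
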