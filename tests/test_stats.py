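import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cfmulti.stats import (
    bh_adjust,
    bootstrap_auc,
    delong_test,
    fisher_exact,
    fit_logistic,
    kruskal_dunn,
    likelihood_ratio_test,
    roc_auc,
    spearman,
    wilcoxon_ranksum,
)


class TestKruskalDunn:
    def test_identical_groups_null(self):
        v = np.r_[np.arange(5.0)]
        values = np.r_[v, v, v]
        groups = np.repeat(["a", "b", "c"], 5)
        res = kruskal_dunn(values, groups)
        assert res.p >= 0.99
        assert all(d["p_adj"] >= d["p"] for d in res.pairwise)

    def test_separated_groups_significant_with_ordered_z(self):
        values = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
        groups = np.repeat(["a", "b", "c"], 3)
        res = kruskal_dunn(values, groups)
        assert res.p < 0.05
        z = {d["pair"]: d["z"] for d in res.pairwise}
        # rank gaps: a-c twice the gap of a-b and b-c
        assert abs(z[("a", "c")]) > abs(z[("a", "b")])
        assert abs(z[("a", "c")]) > abs(z[("b", "c")])
        assert len(res.pairwise) == 3  # all unordered pairs

    def test_tie_corrected_statistic_matches_hand_computation(self):
        values = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        res = kruskal_dunn(values, groups)
        # oracle: direct tie-corrected H formula
        ranks = sps.rankdata(values)
        n = 6
        h = 12 / (n * (n + 1)) * sum(
            (ranks[groups == g].sum()) ** 2 / 3 for g in ("a", "b")
        ) - 3 * (n + 1)
        ties = np.array([2, 1, 2, 1])
        h /= 1 - (ties**3 - ties).sum() / (n**3 - n)
        assert res.statistic == pytest.approx(h)

    def test_dunn_z_matches_direct_rank_arithmetic(self):
        values = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0, 6.0])
        groups = np.array(["a", "a", "a", "b", "b", "b", "c", "c"])
        res = kruskal_dunn(values, groups)
        ranks = sps.rankdata(values)
        n = len(values)
        _, t = np.unique(values, return_counts=True)
        tie_term = np.sum(t**3 - t) / (12 * (n - 1))
        ra = ranks[groups == "a"].mean()
        rb = ranks[groups == "b"].mean()
        se = np.sqrt((n * (n + 1) / 12 - tie_term) * (1 / 3 + 1 / 3))
        z_expected = (ra - rb) / se
        z = {d["pair"]: d["z"] for d in res.pairwise}
        assert z[("a", "b")] == pytest.approx(z_expected)


class TestBasicTests:
    def test_spearman_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 100, 1000, 10000])
        assert rho == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        # oracle: exact hypergeometric sum for the [[5,0],[0,5]] table
        _, p = fisher_exact([[5, 0], [0, 5]])
        # two-sided: tables as or more extreme are [[5,0],[0,5]] and
        # [[0,5],[5,0]], each with probability 1/C(10,5)
        assert p == pytest.approx(2 / 252)

    def test_wilcoxon_identical_samples(self):
        _, p = wilcoxon_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99


class TestBH:
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_rank_order_and_stepup_consistent(self, pvals):
        p = np.array(pvals)
        adj = bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)
        # adjusted p <= alpha must reproduce the step-up rejection set
        for alpha in (0.01, 0.05, 0.25):
            n = p.size
            sorted_p = p[order]
            below = np.flatnonzero(sorted_p <= alpha * (np.arange(n) + 1) / n)
            k = below.max() + 1 if below.size else 0
            rejected = np.zeros(n, bool)
            rejected[order[:k]] = True
            np.testing.assert_array_equal(adj <= alpha + 1e-12, rejected)


class TestLogistic:
    def test_intercept_only_fits_prevalence(self):
        y = np.array([1, 1, 0, 0, 0])
        fit = fit_logistic(y, None)
        np.testing.assert_allclose(fit.fitted, 0.4, atol=1e-6)

    def test_single_binary_predictor_equals_log_odds_ratio(self):
        # oracle: closed form from the 2x2 table (20/10 vs 5/15)
        x = np.r_[np.ones(30), np.zeros(20)]
        y = np.r_[np.ones(20), np.zeros(10), np.ones(5), np.zeros(15)]
        fit = fit_logistic(y, x[:, None], names=["x"])
        log_or = np.log((20 / 10) / (5 / 15))
        sd = x.std()
        assert fit.coef[1] * (1 / sd) * sd == pytest.approx(fit.coef[1])
        # coefficient on the z-scored scale times 1/sd gives the raw slope
        assert fit.coef[1] / sd == pytest.approx(log_or, rel=1e-4)

    def test_deviance_decreases_monotonically_over_irls(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 3))
        y = (rng.random(80) < 0.5).astype(float)
        fit = fit_logistic(y, X)
        assert np.all(np.diff(fit.deviance_path) <= 1e-9)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        X = rng.normal(size=(150, 2))
        eta = -0.3 + X @ np.array([0.8, -1.1])
        y = (rng.random(150) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(y, X)
        Z = (X - X.mean(0)) / X.std(0)
        ref = sm.GLM(y, sm.add_constant(Z), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
        assert fit.deviance == pytest.approx(ref.deviance, abs=1e-6)

    def test_separation_flagged_and_capped(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.copy()
        fit = fit_logistic(y, x[:, None])
        assert fit.separation
        assert np.all(np.abs(fit.coef) <= 15.0 + 1e-9)
        assert fit.deviance < 1.0  # still an excellent fit

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(np.array([0, 1, 0, 1]), np.ones((4, 1)))


class TestLRT:
    def test_identical_models_give_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 2))
        y = (rng.random(60) < 0.5).astype(float)
        fit = fit_logistic(y, X)
        chi2, df, p = likelihood_ratio_test(fit, fit)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_chi2_equals_deviance_difference_and_df_added_columns(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 3))
        eta = X @ np.array([1.0, 0.0, 0.0])
        y = (rng.random(100) < 1 / (1 + np.exp(-eta))).astype(float)
        small = fit_logistic(y, X[:, :1])
        large = fit_logistic(y, X)
        chi2, df, p = likelihood_ratio_test(small, large)
        assert chi2 == pytest.approx(small.deviance - large.deviance)
        assert df == 2
        assert 0 <= p <= 1


class TestROC:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_tied_scores(self):
        auc, _ = roc_auc([1.0, 1.0, 1.0, 1.0], [1, 0, 1, 0])
        assert auc == 0.5

    def test_pair_counting_example(self):
        # oracle: pos {3,5}, neg {1,4}: pairs (3>1), (3<4), (5>1), (5>4) -> 3/4
        auc, _ = roc_auc([3, 5, 1, 4], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            scores = rng.integers(0, 6, 30).astype(float)  # force ties
            labels = rng.integers(0, 2, 30)
            if labels.sum() in (0, 30):
                continue
            auc, _ = roc_auc(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum(1.0 for p in pos for q in neg if p > q)
            ties = sum(0.5 for p in pos for q in neg if p == q)
            assert auc == pytest.approx((wins + ties) / (pos.size * neg.size))

    def test_curve_endpoints(self):
        _, curve = roc_auc([0.9, 0.1, 0.8, 0.3], [1, 0, 1, 0])
        assert tuple(curve[0]) == (0.0, 0.0)
        assert tuple(curve[-1]) == (1.0, 1.0)


class TestDeLong:
    def test_identical_scores_degenerate(self):
        s = np.array([0.9, 0.8, 0.3, 0.2])
        res = delong_test(s, s, np.array([1, 1, 0, 0]))
        assert res["degenerate"] and res["p"] == 1.0

    def test_informative_vs_random_scores_rejected(self):
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            labels = np.r_[np.ones(100), np.zeros(100)].astype(int)
            good = labels + rng.normal(0, 0.7, 200)
            rand = rng.normal(0, 1, 200)
            if delong_test(good, rand, labels)["p"] < 0.05:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_variance_close_to_jackknife(self):
        # oracle: delete-one jackknife variance of the AUC difference
        rng = np.random.default_rng(6)
        labels = np.r_[np.ones(25), np.zeros(25)].astype(int)
        a = labels + rng.normal(0, 1.0, 50)
        b = labels + rng.normal(0, 1.5, 50)
        res = delong_test(a, b, labels)
        se = (res["ci"][1] - res["ci"][0]) / (2 * 1.959963984540054)

        def diff_without(i):
            keep = np.ones(50, bool)
            keep[i] = False
            da, _ = roc_auc(a[keep], labels[keep])
            db, _ = roc_auc(b[keep], labels[keep])
            return da - db

        thetas = np.array([diff_without(i) for i in range(50)])
        jk_var = (50 - 1) / 50 * np.sum((thetas - thetas.mean()) ** 2)
        assert se**2 == pytest.approx(jk_var, rel=0.25)


class TestBootstrap:
    def test_perfect_separation_ci_is_unit(self):
        scores = np.array([0.9, 0.8, 0.85, 0.1, 0.2, 0.15])
        labels = np.array([1, 1, 1, 0, 0, 0])
        res = bootstrap_auc(scores, labels, n_boot=200, seed=0)
        assert res["ci"] == (1.0, 1.0)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        a = bootstrap_auc(scores, labels, n_boot=100, seed=3)
        b = bootstrap_auc(scores, labels, n_boot=100, seed=3)
        assert a["ci"] == b["ci"]

    def test_stratification_preserves_class_counts(self):
        # implied by construction; check CI covers the point AUC typically
        rng = np.random.default_rng(8)
        cover = 0
        for _ in range(20):
            labels = np.r_[np.ones(30), np.zeros(30)].astype(int)
            scores = labels + rng.normal(0, 1, 60)
            auc, _ = roc_auc(scores, labels)
            res = bootstrap_auc(scores, labels, n_boot=200, seed=rng)
            cover += res["ci"][0] <= auc <= res["ci"][1]
        assert cover >= 18
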