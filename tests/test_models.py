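"""Weighted logistic/OLS with cluster-robust SEs, multilevel sensitivity,
scale reliability and predictive validity."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mediapce.models import (
    ClusteredLogit,
    ClusteredOLS,
    RandomInterceptLogit,
    SeparationError,
    adjusted_predictions,
    cluster_robust,
    cronbach_alpha,
    derive_established_smoker,
    derive_intention,
    belief_scale,
    fit_weighted_logistic,
    predictive_validity,
)


def two_by_two_design():
    """x=0: 10/40 events; x=1: 30/40 events -> beta_x = ln 9 exactly."""
    x = np.r_[np.zeros(40), np.ones(40)]
    y = np.r_[np.ones(10), np.zeros(30), np.ones(30), np.zeros(10)]
    return x[:, None], y


def simulate_logit(rng, n=600, n_clusters=None, beta=(0.3, -0.5), icc=0.0):
    X = rng.standard_normal((n, len(beta)))
    eta = -0.4 + X @ np.asarray(beta)
    clusters = None
    if n_clusters:
        clusters = rng.integers(0, n_clusters, n)
        u = rng.normal(0, np.sqrt(icc), n_clusters) if icc > 0 else np.zeros(n_clusters)
        eta = eta + u[clusters]
    y = (rng.random(n) < expit(eta)).astype(float)
    w = rng.lognormal(0, 0.3, n)
    return X, y, w, clusters


class TestWeightedLogit:
    def test_contingency_table_log_odds_ratio_exact(self):
        X, y = two_by_two_design()
        res = fit_weighted_logistic(y, X)
        assert res.params[1] == pytest.approx(np.log(9.0), abs=1e-8)
        assert res.params[0] == pytest.approx(np.log(10 / 30), abs=1e-8)
        assert res.converged

    def test_coefficients_invariant_to_weight_rescaling(self, rng):
        X, y, w, _ = simulate_logit(rng)
        a = fit_weighted_logistic(y, X, weights=w)
        b = fit_weighted_logistic(y, X, weights=2.0 * w)
        np.testing.assert_allclose(a.params, b.params, atol=1e-9)

    def test_matches_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        X, y, w, _ = simulate_logit(rng, n=400)
        mine = ClusteredLogit().fit(X, y, sample_weight=w)
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial(),
                     var_weights=w).fit()
        np.testing.assert_allclose(mine.params_, ref.params, atol=1e-6)

    def test_perfect_separation_raises(self):
        x = np.r_[np.zeros(20), np.ones(20)][:, None]
        y = np.r_[np.zeros(20), np.ones(20)]
        with pytest.raises(SeparationError):
            ClusteredLogit().fit(x, y)

    def test_rank_deficiency_raises(self, rng):
        a = rng.standard_normal(100)
        X = np.column_stack([a, 2 * a])
        y = (rng.random(100) < 0.5).astype(float)
        with pytest.raises(np.linalg.LinAlgError):
            ClusteredLogit().fit(X, y)

    def test_predict_proba_round_trip(self, rng):
        X, y, w, _ = simulate_logit(rng)
        est = ClusteredLogit().fit(X, y, sample_weight=w)
        p = est.predict_proba(X)
        assert p.shape == (len(y), 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)
        assert ((est.predict(X) == 1) == (p[:, 1] >= 0.5)).all()

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = ClusteredLogit(tol=1e-6, max_iter=50)
        assert clone(est).get_params() == est.get_params()


class TestClusterRobust:
    def test_single_obs_clusters_reduce_to_hc_sandwich(self, rng):
        X, y, w, _ = simulate_logit(rng, n=300)
        est = ClusteredLogit().fit(X, y, sample_weight=w, clusters=np.arange(300))
        # hand-built HC sandwich with the matching n/(n-1) factor
        p = est.predict_proba(X)[:, 1]
        M = est._M
        s = M * (w * (y - p))[:, None]
        cov = est._bread @ (s.T @ s) @ est._bread * (300 / 299)
        np.testing.assert_allclose(est.cov_params_, cov, atol=1e-12)

    def test_invariant_to_cluster_relabeling_and_row_order(self, rng):
        X, y, w, cl = simulate_logit(rng, n=500, n_clusters=40, icc=0.3)
        a = ClusteredLogit().fit(X, y, sample_weight=w, clusters=cl)
        relabeled = (cl * 7 + 3) % 101  # injective on 0..40
        b = ClusteredLogit().fit(X, y, sample_weight=w, clusters=relabeled)
        np.testing.assert_allclose(a.bse_, b.bse_, atol=1e-12)
        perm = rng.permutation(len(y))
        c = ClusteredLogit().fit(X[perm], y[perm], sample_weight=w[perm],
                                 clusters=cl[perm])
        np.testing.assert_allclose(a.params_, c.params_, atol=1e-8)
        np.testing.assert_allclose(a.bse_, c.bse_, rtol=1e-6)

    def test_close_to_classical_when_data_independent(self, rng):
        X, y, w, cl = simulate_logit(rng, n=4000, n_clusters=400, icc=0.0)
        clustered = ClusteredLogit().fit(X, y, sample_weight=w, clusters=cl)
        classical = ClusteredLogit().fit(X, y, sample_weight=w)
        ratio = clustered.bse_ / classical.bse_
        np.testing.assert_allclose(ratio, 1.0, atol=0.12)

    def test_single_cluster_rejected(self, rng):
        X, y, w, _ = simulate_logit(rng, n=50)
        with pytest.raises(ValueError, match="at least two clusters"):
            ClusteredLogit().fit(X, y, sample_weight=w, clusters=np.zeros(50))

    def test_refit_free_recompute_matches_fit_time_clusters(self, rng):
        X, y, w, cl = simulate_logit(rng, n=500, n_clusters=40, icc=0.3)
        a = ClusteredLogit().fit(X, y, sample_weight=w, clusters=cl)
        b = ClusteredLogit().fit(X, y, sample_weight=w)
        cluster_robust(b, cl)
        np.testing.assert_allclose(a.bse_, b.bse_, atol=1e-10)


class TestWeightedOLS:
    def test_exact_linear_fit_has_zero_residuals_and_ses(self, rng):
        X = rng.standard_normal((60, 2))
        y = 1.0 + X @ np.array([2.0, -1.0])
        est = ClusteredOLS().fit(X, y, clusters=np.arange(60) % 10)
        np.testing.assert_allclose(est.params_, [1.0, 2.0, -1.0], atol=1e-10)
        np.testing.assert_allclose(est.resid_, 0.0, atol=1e-10)
        np.testing.assert_allclose(est.bse_, 0.0, atol=1e-8)

    def test_equal_weights_match_unweighted(self, rng):
        X = rng.standard_normal((80, 2))
        y = X @ np.array([1.0, 0.5]) + rng.standard_normal(80)
        a = ClusteredOLS().fit(X, y)
        b = ClusteredOLS().fit(X, y, sample_weight=np.full(80, 3.0))
        np.testing.assert_allclose(a.params_, b.params_, atol=1e-10)

    def test_matches_statsmodels_wls_cluster(self, rng):
        import statsmodels.api as sm

        X = rng.standard_normal((200, 2))
        y = X @ np.array([1.0, 0.5]) + rng.standard_normal(200)
        w = rng.lognormal(0, 0.3, 200)
        cl = rng.integers(0, 25, 200)
        mine = ClusteredOLS().fit(X, y, sample_weight=w, clusters=cl)
        ref = sm.WLS(y, sm.add_constant(X), weights=w).fit(
            cov_type="cluster", cov_kwds={"groups": cl}
        )
        np.testing.assert_allclose(mine.params_, ref.params, atol=1e-8)
        # statsmodels additionally applies the regression-df factor
        # (n-1)/(n-k); this package uses the plain G/(G-1) convention
        np.testing.assert_allclose(
            mine.bse_ * np.sqrt(199 / 197), ref.bse, rtol=1e-6
        )


class TestAdjustedPredictions:
    def test_intercept_only_balanced_outcome_gives_half(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        est = ClusteredLogit().fit(pd.DataFrame(index=range(100)), y)
        assert est.params_[0] == pytest.approx(0.0, abs=1e-8)
        assert est.predict_proba(pd.DataFrame(index=range(100)))[0, 1] == pytest.approx(0.5)

    def test_intercept_only_odds_028(self):
        # odds 0.28 -> probability 0.28/1.28 ~ 0.219
        n1 = 280
        y = np.r_[np.ones(n1), np.zeros(1000)]
        est = ClusteredLogit().fit(pd.DataFrame(index=range(len(y))), y)
        assert np.exp(est.params_[0]) == pytest.approx(0.28, abs=1e-6)
        p = est.predict_proba(pd.DataFrame(index=range(1)))[0, 1]
        assert p == pytest.approx(0.28 / 1.28, abs=1e-6)

    def test_negative_interaction_steepens_smoker_curve(self, rng):
        n = 4000
        smoker = (rng.random(n) < 0.3).astype(float)
        anti = rng.standard_normal(n)
        eta = -1.0 + 2.0 * smoker - 0.1 * anti - 0.4 * smoker * anti
        y = (rng.random(n) < expit(eta)).astype(float)
        X = pd.DataFrame({
            "established_smoker": smoker, "anti_index": anti,
            "smoker_x_anti": smoker * anti,
        })
        est = ClusteredLogit().fit(X, y, clusters=rng.integers(0, 100, n))
        grid = np.linspace(-1.5, 1.5, 5)
        out = {
            s: adjusted_predictions(
                est, X, over="anti_index", grid=grid,
                at={"established_smoker": float(s)},
                products={"smoker_x_anti": ("established_smoker", "anti_index")},
            )
            for s in (0, 1)
        }
        drop = {s: out[s]["predicted"].iloc[0] - out[s]["predicted"].iloc[-1] for s in out}
        assert drop[1] > drop[0]  # smokers decline faster in the anti index
        for s in out:
            assert (out[s]["ci_low"] <= out[s]["predicted"]).all()
            assert (out[s]["predicted"] <= out[s]["ci_high"]).all()

    def test_extrapolation_warns(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(200)})
        y = (rng.random(200) < 0.4).astype(float)
        est = ClusteredLogit().fit(X, y, clusters=rng.integers(0, 20, 200))
        with pytest.warns(UserWarning, match="extrapolat"):
            adjusted_predictions(est, X, over="a", grid=[0.0, 99.0])


class TestRandomInterceptLogit:
    def test_reduces_to_plain_logit_when_sigma_zero(self, rng):
        X, y, w, cl = simulate_logit(rng, n=8000, n_clusters=400, icc=0.0)
        ml = RandomInterceptLogit().fit(X, y, clusters=cl)
        plain = ClusteredLogit().fit(X, y)
        assert ml.sigma_ < 0.15
        np.testing.assert_allclose(ml.params_, plain.params_, atol=0.05)

    def test_recovers_cluster_sd_one(self, rng):
        X, y, w, cl = simulate_logit(rng, n=5000, n_clusters=500, icc=1.0)
        ml = RandomInterceptLogit().fit(X, y, clusters=cl)
        assert ml.sigma_ == pytest.approx(1.0, abs=0.2)
        assert ml.converged_

    def test_quadrature_stable_when_nodes_doubled(self, rng):
        X, y, w, cl = simulate_logit(rng, n=1000, n_clusters=100, icc=0.5)
        ml = RandomInterceptLogit(n_quad=15).fit(X, y, clusters=cl)
        ll15 = ml.marginal_loglik()
        ll30 = ml.marginal_loglik(n_quad=30)
        assert abs(ll30 - ll15) < 1e-4

    def test_too_few_clusters_rejected(self, rng):
        X, y, w, cl = simulate_logit(rng, n=50, n_clusters=5)
        with pytest.raises(ValueError, match="at least 10 clusters"):
            RandomInterceptLogit().fit(X, y, clusters=np.arange(50) % 5)


class TestCronbachAlpha:
    def test_identical_items_give_one(self, rng):
        a = rng.standard_normal(100)
        assert cronbach_alpha(np.column_stack([a, a, a])) == pytest.approx(1.0)

    def test_independent_items_near_zero(self, rng):
        X = rng.standard_normal((20_000, 6))
        assert abs(cronbach_alpha(X)) < 0.05

    def test_spearman_brown_closed_form(self, rng):
        # k=12 equicorrelated at r=0.5 -> alpha -> 12*0.5/(1+11*0.5) ~ 0.923
        k, r = 12, 0.5
        common = rng.standard_normal(30_000)
        X = np.sqrt(r) * common[:, None] + np.sqrt(1 - r) * rng.standard_normal((30_000, k))
        assert cronbach_alpha(X) == pytest.approx(k * r / (1 + (k - 1) * r), abs=0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero total variance"):
            cronbach_alpha(np.ones((10, 3)))


class TestPredictiveValidity:
    def test_large_contrast_is_significant(self):
        groups = np.r_[np.zeros(100), np.ones(50)]
        outcomes = np.r_[np.ones(2), np.zeros(98), np.ones(24), np.zeros(26)]
        out = predictive_validity(groups, outcomes)
        assert out["groups"]["0.0"]["proportion"] == pytest.approx(0.02)
        assert out["groups"]["1.0"]["proportion"] == pytest.approx(0.48)
        assert out["p"] < 0.001

    def test_identical_proportions_not_significant(self):
        groups = np.r_[np.zeros(50), np.ones(50)]
        outcomes = np.r_[np.ones(10), np.zeros(40), np.ones(10), np.zeros(40)]
        assert predictive_validity(groups, outcomes)["p"] == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two non-empty groups"):
            predictive_validity(np.zeros(10), np.ones(10))


class TestSurveyDerivations:
    def test_established_smoker_requires_all_three(self):
        out = derive_established_smoker(
            ever_tried=[1, 1, 1, 0], smoked_100=[1, 1, 0, 1], days_smoked_30=[5, 0, 9, 9]
        )
        np.testing.assert_array_equal(out, [1, 0, 0, 0])

    def test_intention_coding_both_branches(self):
        smoker = [0, 0, 1, 1]
        init = ["definitely will not", "probably will not", "", ""]
        quit_ = ["", "", "definitely will", "probably will"]
        # replace blanks with valid placeholders for the unused branch
        init = [i or "definitely will not" for i in init]
        quit_ = [q or "definitely will" for q in quit_]
        out = derive_intention(smoker, init, quit_)
        np.testing.assert_array_equal(out, [0, 1, 0, 1])

    def test_unknown_answer_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            derive_intention([0], ["maybe"], ["definitely will"])

    def test_belief_scale_reverse_coding(self):
        items = pd.DataFrame({"b1": [4, 1], "b2": [4, 1], "b3": [1, 4]})
        s = belief_scale(items, reverse=["b3"])
        np.testing.assert_allclose(s, [4.0, 1.0])
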