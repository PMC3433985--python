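"""Firth logistic, AIC subsets, AUC, Poisson GLMM, MANOVA."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from landlock.habitat import (
    all_subsets_aic, auc, firth_logistic, firth_penalized_loglik, glmm_fitter,
    manova_wilks, poisson_glmm, poisson_glmm_loglik,
)
from oracles import (
    auc_all_pairs, firth_fit_by_optimizer, firth_loglik_direct,
    poisson_glmm_loglik_plain_gh,
)


class TestFirth:
    def test_complete_separation_gives_finite_estimates(self):
        y = np.array([0, 0, 1, 1])
        x = np.array([[0.0], [0.0], [1.0], [1.0]])
        fit = firth_logistic(y, x)
        assert np.isfinite(fit.coefficients).all()
        assert fit.converged
        assert fit.coefficients["x0"] > 0
        # the unpenalised MLE diverges here; the penalised one is modest
        assert abs(fit.coefficients["x0"]) < 10

    def test_constant_zero_response(self):
        fit = firth_logistic(np.zeros(6), np.arange(6.0)[:, None])
        assert np.isfinite(fit.coefficients["intercept"])
        assert fit.coefficients["intercept"] < 0

    def test_matches_direct_penalized_likelihood_optimum(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(12, 2))
        y = (x[:, 0] + rng.normal(0, 1, 12) > 0).astype(float)
        fit = firth_logistic(y, x)
        X = np.column_stack([np.ones(12), x])
        beta_opt = firth_fit_by_optimizer(X, y)
        assert np.allclose(
            fit.coefficients.to_numpy(), beta_opt, atol=1e-4
        )
        # and the two penalised-likelihood implementations agree at the optimum
        assert firth_penalized_loglik(beta_opt, X, y) == pytest.approx(
            firth_loglik_direct(beta_opt, X, y), abs=1e-9
        )

    def test_finite_on_random_separated_designs(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            x = rng.normal(size=(15, 3))
            y = (x[:, 0] > 0).astype(float)  # separation on column 0
            fit = firth_logistic(y, x)
            assert np.isfinite(fit.coefficients).all()

    def test_rank_deficiency_reported(self):
        x = np.ones((8, 2))
        x[:, 1] = 2 * x[:, 0]
        with pytest.raises(ValueError, match="collinear"):
            firth_logistic(np.array([0, 1] * 4, dtype=float), x)

    def test_aic_identity(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(20, 2))
        y = (rng.random(20) < 0.5).astype(float)
        fit = firth_logistic(y, x)
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * 3)


class TestAllSubsets:
    def frame(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"u": rng.normal(size=n), "v": rng.normal(size=n)})
        df["y"] = (df["u"] + rng.normal(0, 0.5, n) > 0).astype(float)
        return df

    def test_pool_of_two_matches_manual_ranking(self):
        df = self.frame()
        best, table = all_subsets_aic(df, "y", predictor_pool=("u", "v"))
        manual = {}
        for preds in [(), ("u",), ("v",), ("u", "v")]:
            manual[preds] = firth_logistic(
                df["y"].to_numpy(), df, preds
            ).aic
        assert len(table) == 4
        for _, row in table.iterrows():
            assert row["aic"] == pytest.approx(manual[tuple(row["predictors"])])
        assert set(best.predictors) == set(
            min(manual, key=manual.get)
        )

    def test_null_only_pool_returns_intercept_model(self):
        df = self.frame()
        best, table = all_subsets_aic(df, "y", predictor_pool=())
        assert best.predictors == ()
        assert len(table) == 1

    def test_ranking_invariant_to_predictor_order(self):
        df = self.frame(seed=3)
        best_a, _ = all_subsets_aic(df, "y", predictor_pool=("u", "v"))
        best_b, _ = all_subsets_aic(df, "y", predictor_pool=("v", "u"))
        assert set(best_a.predictors) == set(best_b.predictors)
        assert best_a.aic == pytest.approx(best_b.aic)

    def test_true_predictor_selected_under_noise(self):
        # one strong real effect among pure-noise predictors
        hits = 0
        reps = 60
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            n = 60
            df = pd.DataFrame(
                {f"n{i}": rng.normal(size=n) for i in range(3)}
                | {"signal": rng.normal(size=n)}
            )
            eta = -0.3 + 2.5 * df["signal"]
            df["y"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            best, _ = all_subsets_aic(
                df, "y", predictor_pool=("n0", "n1", "n2", "signal")
            )
            if "signal" in best.predictors:
                hits += 1
        assert hits / reps >= 0.9


class TestAuc:
    def test_perfect_and_constant(self):
        y = np.array([0, 0, 1, 1])
        assert auc([0.1, 0.2, 0.8, 0.9], y) == 1.0
        assert auc([0.5] * 4, y) == 0.5

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 25)
        y[0], y[1] = 0, 1
        scores = np.round(rng.random(25), 1)  # ties likely
        assert auc(scores, y) == pytest.approx(auc_all_pairs(scores, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        scores = rng.random(30)
        assert auc(scores, y) == pytest.approx(auc(np.exp(3 * scores), y))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc([0.2, 0.8], [1, 1])


class TestPoissonGlmm:
    def simulate(self, sigma, seed=0, n_rivers=3, per=8):
        rng = np.random.default_rng(seed)
        n = n_rivers * per
        x = rng.normal(size=n)
        g = np.repeat(np.arange(n_rivers), per)
        b = rng.normal(0, sigma, n_rivers)
        y = rng.poisson(np.exp(1.0 + 0.5 * x + b[g]))
        return pd.DataFrame({"x": x}), y, g

    def test_zero_variance_truth_matches_plain_glm(self):
        df, y, g = self.simulate(sigma=0.0, seed=1)
        fit = poisson_glmm(y, df, ["x"], g)
        glm = sm.GLM(y, sm.add_constant(df["x"]), family=sm.families.Poisson()).fit()
        assert fit.random_effect_sd == pytest.approx(0.0, abs=0.05)
        assert np.allclose(fit.coefficients.to_numpy(), glm.params, atol=1e-3)

    def test_single_river_reduces_to_glm(self):
        df, y, _ = self.simulate(sigma=0.0, seed=2, n_rivers=1, per=25)
        fit = poisson_glmm(y, df, ["x"], np.zeros(25, dtype=int))
        glm = sm.GLM(y, sm.add_constant(df["x"]), family=sm.families.Poisson()).fit()
        assert np.allclose(fit.coefficients.to_numpy(), glm.params, atol=1e-3)
        assert fit.log_likelihood == pytest.approx(glm.llf, abs=1e-3)

    def test_adaptive_quadrature_matches_refined(self):
        df, y, g = self.simulate(sigma=0.4, seed=3)
        X = np.column_stack([np.ones(len(y)), df["x"].to_numpy()])
        beta = np.array([1.0, 0.5])
        ll8 = poisson_glmm_loglik(beta, 0.4, y.astype(float), X, g, n_nodes=8)
        ll64 = poisson_glmm_loglik(beta, 0.4, y.astype(float), X, g, n_nodes=64)
        assert ll8 == pytest.approx(ll64, abs=1e-6)
        # and against a non-adaptive high-order quadrature written separately
        ll_plain = poisson_glmm_loglik_plain_gh(beta, 0.4, y.astype(float), X, g)
        assert ll8 == pytest.approx(ll_plain, abs=1e-6)

    def test_non_integer_counts_rejected(self):
        df = pd.DataFrame({"x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            poisson_glmm(np.array([1.5, 2.0]), df, ["x"], [0, 1])

    def test_subset_selection_via_shared_machinery(self):
        df, y, g = self.simulate(sigma=0.3, seed=4)
        df = df.assign(noise=np.random.default_rng(5).normal(size=len(df)))
        df["rich"] = y
        best, table = all_subsets_aic(
            df, "rich", predictor_pool=("x", "noise"), fitter=glmm_fitter(g)
        )
        assert "x" in best.predictors
        assert len(table) == 4


class TestManova:
    def test_toy_determinant_ratio(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(10, 2))
        labels = np.array([0] * 5 + [1] * 5)
        res = manova_wilks(x, labels)
        xc = x - x.mean(axis=0)
        T = xc.T @ xc
        W = np.zeros((2, 2))
        for g in (0, 1):
            gc = x[labels == g] - x[labels == g].mean(axis=0)
            W += gc.T @ gc
        lam = np.linalg.det(W) / np.linalg.det(T)
        assert res.wilks_lambda == pytest.approx(lam, rel=1e-10)
        # two groups: Rao's F on (p, n-p-1) df
        assert res.df == (2, 7)
        assert res.F == pytest.approx((1 - lam) / lam * 7 / 2, rel=1e-10)

    def test_statsmodels_agreement(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(16, 3))
        labels = np.array([0] * 8 + [1] * 8)
        res = manova_wilks(x, labels)
        mv = sm.multivariate.MANOVA(x, sm.add_constant(labels)).mv_test()
        table = mv.results["x1"]["stat"]
        assert res.wilks_lambda == pytest.approx(
            float(table.loc["Wilks' lambda", "Value"]), rel=1e-8
        )
        assert res.p == pytest.approx(
            float(table.loc["Wilks' lambda", "Pr > F"]), rel=1e-6
        )

    def test_perfectly_separated_coordinate(self):
        x = np.zeros((8, 2))
        x[:4, 0] = 1.0  # group 0 all 1, group 1 all 0, zero within variance
        x[:, 1] = np.arange(8) * 0.1
        res = manova_wilks(x, np.array([0] * 4 + [1] * 4))
        assert res.wilks_lambda == pytest.approx(0.0, abs=1e-12)

    def test_null_lambda_near_one_for_large_n(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(200, 4))
        labels = (np.arange(200) % 2 == 0).astype(int)
        res = manova_wilks(x, labels)
        assert res.wilks_lambda > 0.9
        assert res.p > 0.01
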