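"""Penalty tuning, KKT optimality, CI-rule significance, cross-prediction."""

import numpy as np
import pytest

from aggnet.ensemble import (
    EnsembleConfig,
    PredictionMetrics,
    cross_predict,
    fit_at_lambda,
    overlap_and_restrict,
    predict_with_mean_betas,
    run_ensemble,
    tune_lambda_cv,
)
from aggnet.preprocess import make_splits


@pytest.fixture(scope="module")
def planted():
    """n=600, 20 noise features, one planted standardized effect of 0.5."""
    rng = np.random.default_rng(0)
    n, p = 600, 21
    X = rng.standard_normal((n, p))
    y = 0.5 * X[:, 0] + np.sqrt(0.75) * rng.standard_normal(n)
    return X, y


@pytest.fixture(scope="module")
def small_model(planted):
    X, y = planted
    splits = make_splits(len(y), n_repeats=25, seed=1)
    model = run_ensemble(
        X[splits.discovery_idx],
        y[splits.discovery_idx],
        splits,
        EnsembleConfig(n_repeats=25, seed=2),
    )
    return model, splits, X, y


class TestTuneLambda:
    def test_pure_noise_prefers_heavy_shrinkage(self):
        cfg = EnsembleConfig()
        lams = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((300, 20))
            y = rng.standard_normal(300)
            lam, _ = tune_lambda_cv(X, y, cfg, seed=seed)
            lams.append(lam)
        assert np.median(lams) > 0.05

    def test_strong_clean_signal_prefers_light_shrinkage(self):
        cfg = EnsembleConfig()
        rng = np.random.default_rng(1)
        X = rng.standard_normal((400, 10))
        beta = rng.uniform(0.5, 1.0, 10)
        y = X @ beta  # noiseless
        lam, curve = tune_lambda_cv(X, y, cfg, seed=0)
        # the CV curve plateaus at solver precision for small penalties; the
        # chosen penalty must sit deep in the light-shrinkage tail of the grid
        assert lam < 0.01
        assert curve[-1] == pytest.approx(curve.min())

    def test_lambda_one_shrinks_everything_to_the_mean(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 15))
        y = (X[:, 0] - X[:, 0].mean()) / X[:, 0].std()
        beta, icpt = fit_at_lambda(X, y, 1.0)
        assert np.abs(beta).max() < 0.05
        pred = X @ beta + icpt
        assert np.abs(pred - y.mean()).max() < 0.2

    def test_zero_variance_outcome_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            tune_lambda_cv(rng.standard_normal((50, 3)), np.ones(50), EnsembleConfig())


class TestKktOptimality:
    @pytest.mark.parametrize("lam", [0.01, 0.1, 0.4])
    def test_coordinate_descent_solution_satisfies_kkt(self, lam):
        rng = np.random.default_rng(4)
        n, p = 400, 12
        X = rng.standard_normal((n, p))
        y = X[:, 0] * 0.6 + rng.standard_normal(n)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta, _ = fit_at_lambda(X, y, lam)
        grad = Xc.T @ (yc - Xc @ beta) / n
        active = np.abs(beta) > 1e-12
        assert np.all(np.abs(grad[~active]) <= lam + 1e-6)
        np.testing.assert_allclose(
            grad[active], lam * np.sign(beta[active]), atol=1e-6
        )

    def test_elastic_net_at_full_l1_reproduces_lasso(self):
        from sklearn.linear_model import enet_path

        rng = np.random.default_rng(5)
        X = rng.standard_normal((300, 10))
        y = X[:, 1] - X[:, 3] + rng.standard_normal(300)
        b_lasso, _ = fit_at_lambda(X, y, 0.05, l1_ratio=1.0)
        Xc, yc = X - X.mean(axis=0), y - y.mean()
        _, coefs, _ = enet_path(Xc, yc, alphas=np.array([0.05]), l1_ratio=1.0, tol=1e-8)
        np.testing.assert_allclose(b_lasso, coefs[:, 0], atol=1e-6)


class TestAgainstGlmnet:
    def test_lasso_solution_matches_glmnet_reference(self, tmp_path):
        """Independent oracle: R glmnet at the same penalty and scaling."""
        import subprocess

        rng = np.random.default_rng(11)
        n, p, lam = 250, 8, 0.08
        X = rng.standard_normal((n, p))
        y = 0.7 * X[:, 0] - 0.4 * X[:, 4] + rng.standard_normal(n)
        np.savetxt(tmp_path / "X.txt", X)
        np.savetxt(tmp_path / "y.txt", y)
        script = f"""
X <- as.matrix(read.table('{tmp_path}/X.txt'))
y <- scan('{tmp_path}/y.txt')
library(glmnet)
fit <- glmnet(X, y, alpha=1, lambda={lam}, standardize=FALSE,
              intercept=TRUE, thresh=1e-12)
cat(sprintf('%.10f', as.numeric(coef(fit))), sep='\\n')
"""
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ref = np.array([float(v) for v in out.stdout.split()])
        beta, icpt = fit_at_lambda(X, y, lam)
        assert icpt == pytest.approx(ref[0], abs=1e-4)
        np.testing.assert_allclose(beta, ref[1:], atol=1e-4)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.linspace(-1, 1, 30)
        m = PredictionMetrics.from_predictions(y, y)
        assert m.r == pytest.approx(1.0)
        assert m.rmse == 0.0
        assert m.mae == 0.0

    def test_r_squared_is_squared_r(self):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(100)
        pred = y + rng.standard_normal(100)
        m = PredictionMetrics.from_predictions(y, pred)
        assert m.r_squared == pytest.approx(m.r**2, abs=1e-12)
        assert m.rmse >= m.mae >= 0

    def test_constant_prediction_flagged_degenerate(self):
        y = np.linspace(0, 1, 20)
        m = PredictionMetrics.from_predictions(y, np.zeros(20))
        assert m.degenerate
        assert np.isnan(m.r)


class TestEnsemble:
    def test_planted_feature_flagged_significant(self, small_model):
        model, _, _, _ = small_model
        assert model.significance_mask[0]
        assert model.mean_significant_beta[0] > 0.2

    def test_mean_beta_zero_off_mask(self, small_model):
        model, _, _, _ = small_model
        assert np.all(model.mean_significant_beta[~model.significance_mask] == 0.0)
        mean_all = model.betas.mean(axis=0)
        assert np.all(model.ci_low <= mean_all + 1e-12)
        assert np.all(mean_all <= model.ci_high + 1e-12)

    def test_holdout_prediction_recovers_signal(self, small_model):
        model, splits, X, y = small_model
        yd = y[splits.discovery_idx]
        yh = (y[splits.holdout_idx] - yd.mean()) / yd.std(ddof=1)
        m = predict_with_mean_betas(model, X[splits.holdout_idx], yh)
        assert m.r > 0.3

    def test_all_zero_betas_not_significant(self):
        # heavy noise, tiny signal: most features end up with all-zero betas
        rng = np.random.default_rng(7)
        n = 300
        X = rng.standard_normal((n, 10))
        y = rng.standard_normal(n)
        splits = make_splits(n, n_repeats=12, seed=8)
        model = run_ensemble(
            X[splits.discovery_idx], y[splits.discovery_idx], splits,
            EnsembleConfig(n_repeats=12, seed=9),
        )
        all_zero = np.all(model.betas == 0.0, axis=0)
        assert not model.significance_mask[all_zero].any()

    def test_elastic_net_ensemble_variant_runs_and_recovers(self, planted):
        X, y = planted
        splits = make_splits(len(y), n_repeats=8, seed=3)
        model = run_ensemble(
            X[splits.discovery_idx], y[splits.discovery_idx], splits,
            EnsembleConfig(
                n_repeats=8, seed=4, penalty="elastic_net", alpha_grid=(0.5, 1.0)
            ),
        )
        assert model.significance_mask[0]
        assert set(np.unique(model.best_mixings)) <= {0.5, 1.0}

    def test_feature_mismatch_rejected(self, small_model):
        model, _, X, _ = small_model
        with pytest.raises(ValueError):
            predict_with_mean_betas(model, X[:, :-1], np.zeros(len(X)))


class TestOverlap:
    def test_mask_intersection(self, small_model):
        model, _, _, _ = small_model
        other = model.restrict(np.ones_like(model.significance_mask))
        overlap, ra, rb = overlap_and_restrict(model, other)
        expected = [
            n
            for n, m in zip(model.feature_names, model.significance_mask)
            if m
        ]
        assert overlap == expected

    def test_restricting_to_own_mask_leaves_predictions_unchanged(self, small_model):
        model, splits, X, y = small_model
        restricted = model.restrict(model.significance_mask)
        yd = y[splits.discovery_idx]
        yh = (y[splits.holdout_idx] - yd.mean()) / yd.std(ddof=1)
        a = predict_with_mean_betas(model, X[splits.holdout_idx], yh)
        b = predict_with_mean_betas(restricted, X[splits.holdout_idx], yh)
        assert a.r == pytest.approx(b.r)
        assert a.rmse == pytest.approx(b.rmse)

    def test_cross_prediction_on_own_outcome_matches_own_metrics(self, small_model):
        model, splits, X, y = small_model
        yd = y[splits.discovery_idx]
        yh = (y[splits.holdout_idx] - yd.mean()) / yd.std(ddof=1)
        own = predict_with_mean_betas(model, X[splits.holdout_idx], yh)
        crossed = cross_predict(model, X[splits.holdout_idx], yh)
        assert crossed.r == pytest.approx(own.r)

    def test_empty_overlap_warns(self, small_model):
        model, _, _, _ = small_model
        none = model.restrict(np.zeros_like(model.significance_mask))
        with pytest.warns(UserWarning, match="empty overlap"):
            overlap, _, _ = overlap_and_restrict(model, none)
        assert overlap == []
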