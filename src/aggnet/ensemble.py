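"""Repeated-subsampling penalized regression ensembles.

The workflow, per outcome: split the discovery sample repeatedly into inner
train/test partitions; per repeat, standardize and impute with training
statistics, tune the L1 penalty on a fixed geometric grid over [1e-10, 1] by
10-fold cross-validated RMSE, fit the LASSO at the chosen penalty, and record
the coefficients on the standardized design. Across the (default 100)
repeats, a feature is declared significant when the percentile 95% interval
of its coefficients excludes zero — a stability heuristic, not a calibrated
test. Significant features keep their mean coefficient; the rest are zeroed.
The averaged coefficient vector predicts the holdout sample, predicts the
*other* outcome for cross-prediction, and its significance mask intersects
with the other model's mask to define the overlap feature set.

LASSO solutions come from scikit-learn's coordinate descent
(``lasso_path`` / ``enet_path``), whose objective (1/(2n))||y - Xb||^2 +
lambda ||b||_1 matches the KKT conditions asserted in the tests. The Elastic
Net variant adds a mixing-parameter grid and reproduces the LASSO exactly at
mixing 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer
from sklearn.linear_model import enet_path, lasso_path
from sklearn.model_selection import KFold

from .outcomes import pearson_with_p
from .preprocess import PreprocessPlan, SplitPlan


@dataclass(frozen=True)
class EnsembleConfig:
    n_repeats: int = 100
    cv_folds: int = 10
    lambda_min: float = 1e-10
    lambda_max: float = 1.0
    n_lambdas: int = 100
    penalty: str = "lasso"  # or "elastic_net"
    alpha_grid: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)  # L1 mixing values
    ci_level: float = 0.95
    min_success_frac: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.penalty not in ("lasso", "elastic_net"):
            raise ValueError(f"unknown penalty {self.penalty!r}")
        if self.lambda_min <= 0 or self.lambda_max <= self.lambda_min:
            raise ValueError("lambda grid endpoints invalid")

    @property
    def lambda_grid(self) -> np.ndarray:
        """Geometric grid, descending (as coordinate-descent paths expect)."""
        return np.geomspace(self.lambda_max, self.lambda_min, self.n_lambdas)


@dataclass
class PredictionMetrics:
    """Holdout/test metrics on the standardized-outcome scale."""

    r: float
    r_squared: float
    rmse: float
    mae: float
    p_value: float = float("nan")
    degenerate: bool = False

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "PredictionMetrics":
        y_true = np.asarray(y_true, float)
        y_pred = np.asarray(y_pred, float)
        rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
        mae = float(np.mean(np.abs(y_true - y_pred)))
        if np.std(y_pred) == 0 or np.std(y_true) == 0:
            return cls(float("nan"), float("nan"), rmse, mae, degenerate=True)
        r, p = pearson_with_p(y_true, y_pred)
        return cls(r=r, r_squared=r * r, rmse=rmse, mae=mae, p_value=p)

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "mae": self.mae,
            "degenerate": self.degenerate,
        }


@dataclass
class EnsembleModel:
    """Per-repeat coefficients and the CI-based significance summary."""

    feature_names: list[str]
    betas: np.ndarray  # repeats x features, standardized design scale
    intercepts: np.ndarray
    best_lambdas: np.ndarray
    best_mixings: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    significance_mask: np.ndarray
    mean_significant_beta: np.ndarray
    test_metrics: list[PredictionMetrics] = field(default_factory=list)
    n_failed: int = 0

    @property
    def n_significant(self) -> int:
        return int(self.significance_mask.sum())

    @property
    def mean_intercept(self) -> float:
        return float(self.intercepts.mean()) if self.intercepts.size else 0.0

    def restrict(self, mask: np.ndarray) -> "EnsembleModel":
        """Zero every averaged coefficient outside ``mask`` (no refit)."""
        mask = np.asarray(mask, bool)
        new_mask = self.significance_mask & mask
        new_beta = np.where(new_mask, self.mean_significant_beta, 0.0)
        return replace(self, significance_mask=new_mask, mean_significant_beta=new_beta)

    def to_json(self, path) -> None:
        import json

        payload = {
            "feature_names": self.feature_names,
            "betas": self.betas.tolist(),
            "intercepts": self.intercepts.tolist(),
            "best_lambdas": self.best_lambdas.tolist(),
            "ci_low": self.ci_low.tolist(),
            "ci_high": self.ci_high.tolist(),
            "significance_mask": self.significance_mask.astype(int).tolist(),
            "mean_significant_beta": self.mean_significant_beta.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _path_fit(X, y, lambdas, l1_ratio=1.0, tol=1e-4):
    """Coefficient path at the given penalties, with intercepts.

    Centers X and y (the path solvers fit no intercept), returns
    (coefs [p x L], intercepts [L]) aligned with ``lambdas``.
    """
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    # Fortran order + check_input=False skips sklearn's per-alpha validation,
    # which otherwise dominates the runtime of repeated path fits
    Xc = np.asfortranarray(X - x_mean, dtype=np.float64)
    yc = np.ascontiguousarray(y - y_mean, dtype=np.float64)
    lambdas = np.asarray(lambdas, dtype=np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if l1_ratio == 1.0:
            _, coefs, _ = lasso_path(Xc, yc, alphas=lambdas, tol=tol, check_input=False)
        else:
            _, coefs, _ = enet_path(
                Xc, yc, alphas=lambdas, l1_ratio=l1_ratio, tol=tol, check_input=False
            )
    intercepts = y_mean - x_mean @ coefs
    return coefs, intercepts


def tune_lambda_cv(
    X: np.ndarray,
    y: np.ndarray,
    config: EnsembleConfig,
    seed: int = 0,
    l1_ratio: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Pick the penalty minimizing mean out-of-fold RMSE on the grid.

    Returns (best_lambda, cv_rmse aligned with ``config.lambda_grid``); ties
    resolve toward heavier shrinkage (the grid is descending, so the first
    minimum wins).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.shape[0] < config.cv_folds:
        raise ValueError("fewer rows than CV folds")
    if y.std() == 0:
        raise ValueError("outcome has zero variance")
    lambdas = config.lambda_grid
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    sq_err = np.zeros(len(lambdas))
    n_total = 0
    for tr, va in kf.split(X):
        coefs, intercepts = _path_fit(X[tr], y[tr], lambdas, l1_ratio)
        preds = X[va] @ coefs + intercepts[None, :]
        sq_err += ((preds - y[va][:, None]) ** 2).sum(axis=0)
        n_total += len(va)
    cv_rmse = np.sqrt(sq_err / n_total)
    best = int(np.argmin(cv_rmse))
    return float(lambdas[best]), cv_rmse


def fit_at_lambda(
    X: np.ndarray, y: np.ndarray, lam: float, l1_ratio: float = 1.0
) -> tuple[np.ndarray, float]:
    """Single coordinate-descent fit at one penalty; returns (beta, intercept).

    Run at a tight convergence tolerance so the solution satisfies the KKT
    stationarity conditions to ~1e-6.
    """
    coefs, intercepts = _path_fit(
        np.asarray(X, float), np.asarray(y, float), np.array([lam]), l1_ratio,
        tol=1e-8,
    )
    return coefs[:, 0], float(intercepts[0])


def _standardize_impute(
    X_train: np.ndarray, plan_k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, KNNImputer | None]:
    """Per-repeat preprocessing on an already-encoded numeric matrix."""
    obs = ~np.isnan(X_train)
    n_obs = obs.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        means = np.nanmean(X_train, axis=0)
        sds = np.nanstd(X_train, axis=0, ddof=1)
    keep = (n_obs > 0) & (sds > 0) & np.isfinite(sds)
    means = np.where(keep, means, 0.0)
    sds = np.where(keep, sds, 1.0)
    Z = (X_train - means) / sds
    Z[:, ~keep] = 0.0
    imputer = None
    if np.isnan(Z).any():
        k = min(plan_k, max(1, Z.shape[0] - 1))
        imputer = KNNImputer(n_neighbors=k, weights="uniform")
        Z = imputer.fit_transform(Z)
    return Z, keep, means, sds, imputer


def run_ensemble(
    X_discovery: pd.DataFrame | np.ndarray,
    y_discovery: np.ndarray,
    splits: SplitPlan,
    config: EnsembleConfig,
    plan: PreprocessPlan | None = None,
) -> EnsembleModel:
    """Fit the repeated-subsampling ensemble on the discovery sample.

    ``X_discovery`` is the encoded (numeric, possibly NaN-holding) discovery
    feature matrix; per repeat the scaling/imputation statistics are refitted
    on the inner-train rows only. Coefficients are aligned to the discovery
    column layout, with zeros for columns dropped in a given repeat.
    """
    if plan is None:
        plan = PreprocessPlan()
    if isinstance(X_discovery, pd.DataFrame):
        names = list(X_discovery.columns)
        X = X_discovery.to_numpy(dtype=float)
    else:
        X = np.asarray(X_discovery, dtype=float)
        names = [f"f{i + 1}" for i in range(X.shape[1])]
    y = np.asarray(y_discovery, dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("X and y row counts differ")
    n_rep = splits.n_repeats
    p = X.shape[1]
    betas = np.zeros((n_rep, p))
    intercepts = np.zeros(n_rep)
    best_lambdas = np.zeros(n_rep)
    best_mixings = np.ones(n_rep)
    ok = np.zeros(n_rep, dtype=bool)
    test_metrics: list[PredictionMetrics] = []
    mix_grid = config.alpha_grid if config.penalty == "elastic_net" else (1.0,)
    for r, (tr, te) in enumerate(splits.repeat_splits):
        try:
            Ztr, keep, means, sds, imputer = _standardize_impute(X[tr], plan.knn_k)
            y_mean, y_sd = y[tr].mean(), y[tr].std(ddof=1)
            if y_sd == 0:
                raise ValueError("inner-train outcome has zero variance")
            ytr = (y[tr] - y_mean) / y_sd
            rep_seed = (config.seed * 100_003 + r) % (2**31)
            best_rmse, best_lam, best_mix = np.inf, None, 1.0
            for mix in mix_grid:
                lam, curve = tune_lambda_cv(Ztr, ytr, config, seed=rep_seed, l1_ratio=mix)
                if curve.min() < best_rmse:
                    best_rmse, best_lam, best_mix = curve.min(), lam, mix
            beta_k, icpt = fit_at_lambda(Ztr, ytr, best_lam, best_mix)
            # inner-test metrics with the repeat-fitted preprocessing
            Zte = (X[te] - means) / sds
            Zte[:, ~keep] = 0.0
            if np.isnan(Zte).any():
                Zte = imputer.transform(Zte) if imputer is not None else np.nan_to_num(Zte)
            yte = (y[te] - y_mean) / y_sd
            pred = Zte @ beta_k + icpt
            test_metrics.append(PredictionMetrics.from_predictions(yte, pred))
            betas[r] = beta_k
            intercepts[r] = icpt
            best_lambdas[r] = best_lam
            best_mixings[r] = best_mix
            ok[r] = True
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"repeat {r} failed and was skipped: {exc}")
    n_ok = int(ok.sum())
    if n_ok < config.min_success_frac * n_rep:
        raise RuntimeError(f"only {n_ok}/{n_rep} repeats succeeded")
    B = betas[ok]
    lo_q = 100 * (1 - config.ci_level) / 2
    ci_low = np.percentile(B, lo_q, axis=0)
    ci_high = np.percentile(B, 100 - lo_q, axis=0)
    mask = (ci_low > 0) | (ci_high < 0)
    mean_beta = B.mean(axis=0)
    mean_sig = np.where(mask, mean_beta, 0.0)
    return EnsembleModel(
        feature_names=names,
        betas=B,
        intercepts=intercepts[ok],
        best_lambdas=best_lambdas[ok],
        best_mixings=best_mixings[ok],
        ci_low=ci_low,
        ci_high=ci_high,
        significance_mask=mask,
        mean_significant_beta=mean_sig,
        test_metrics=test_metrics,
        n_failed=n_rep - n_ok,
    )


def predict_with_mean_betas(
    model: EnsembleModel,
    X_new: pd.DataFrame | np.ndarray,
    y_new: np.ndarray,
) -> PredictionMetrics:
    """Score new data with the averaged significant coefficients.

    ``X_new`` must be the design produced by the discovery-fitted transform
    (same columns, standardized); ``y_new`` standardized comparably.
    """
    if isinstance(X_new, pd.DataFrame):
        if list(X_new.columns) != model.feature_names:
            raise ValueError("feature columns do not match the fitted design")
        X_new = X_new.to_numpy(dtype=float)
    X_new = np.asarray(X_new, float)
    if X_new.shape[1] != len(model.feature_names):
        raise ValueError("feature count does not match the fitted design")
    y_pred = X_new @ model.mean_significant_beta + model.mean_intercept
    return PredictionMetrics.from_predictions(np.asarray(y_new, float), y_pred)


def cross_predict(
    model_a: EnsembleModel,
    X_holdout: pd.DataFrame | np.ndarray,
    y_other: np.ndarray,
) -> PredictionMetrics:
    """Apply model A's averaged coefficients, score against the other outcome."""
    return predict_with_mean_betas(model_a, X_holdout, y_other)


def overlap_and_restrict(
    model_a: EnsembleModel, model_b: EnsembleModel
) -> tuple[list[str], EnsembleModel, EnsembleModel]:
    """Intersect significance masks; zero both models outside the overlap."""
    if model_a.feature_names != model_b.feature_names:
        raise ValueError("models were fitted on different designs")
    overlap_mask = model_a.significance_mask & model_b.significance_mask
    overlap = [n for n, m in zip(model_a.feature_names, overlap_mask) if m]
    if not overlap:
        warnings.warn("empty overlap between the two models")
    return overlap, model_a.restrict(overlap_mask), model_b.restrict(overlap_mask)
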