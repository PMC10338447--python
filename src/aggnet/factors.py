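"""Factor reduction: parallel analysis, minres extraction, oblimin rotation.

The overlap features surviving both penalized ensembles are reduced to a
small number of oblique factors before network estimation. The number of
factors comes from parallel analysis on the reduced correlation matrix
(squared multiple correlations on the diagonal), comparing observed
eigenvalues against the mean (or an upper quantile) of eigenvalues from
size-matched random normal data. Extraction is minimum-residual: uniquenesses
are optimized so the rank-k approximation of the reduced correlation matrix
minimizes the sum of squared off-diagonal residuals. Rotation is oblimin
(direct quartimin at gamma=0) via gradient projection, which allows the
factors to correlate — required downstream, where edges are partial
correlations. Factor scores are regression (Thurstone) scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


# ---------------------------------------------------------------------------
# Parallel analysis


def _reduced_eigenvalues(R: np.ndarray) -> np.ndarray:
    """Eigenvalues of the correlation matrix with SMCs on the diagonal."""
    p = R.shape[0]
    try:
        Rinv = np.linalg.inv(R)
        smc = 1.0 - 1.0 / np.diag(Rinv)
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.9)
    Rr = R.copy()
    np.fill_diagonal(Rr, np.clip(smc, 0.0, 1.0))
    return np.sort(np.linalg.eigvalsh(Rr))[::-1]


def parallel_analysis(
    X: np.ndarray,
    n_resamples: int = 100,
    seed: int = 0,
    criterion: str = "mean",
) -> int:
    """Number of factors whose eigenvalues beat size-matched random data.

    Counts the leading observed factor-model eigenvalues that exceed the
    reference eigenvalues from ``n_resamples`` random standard-normal
    datasets of the same shape, stopping at the first failure. ``criterion``
    is the aggregation of the random eigenvalues: ``"mean"`` (default) or
    ``"p95"`` for the 95th percentile.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p >= n:
        raise ValueError("parallel analysis requires more participants than features")
    obs = _reduced_eigenvalues(np.corrcoef(X, rowvar=False))
    rng = np.random.default_rng(seed)
    rand = np.empty((n_resamples, p))
    for b in range(n_resamples):
        Z = rng.standard_normal((n, p))
        rand[b] = _reduced_eigenvalues(np.corrcoef(Z, rowvar=False))
    if criterion == "mean":
        ref = rand.mean(axis=0)
    elif criterion == "p95":
        ref = np.quantile(rand, 0.95, axis=0)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    n_factors = 0
    for lam_obs, lam_ref in zip(obs, ref):
        if lam_obs > lam_ref:
            n_factors += 1
        else:
            break
    return n_factors


# ---------------------------------------------------------------------------
# Minimum-residual extraction


def _minres_loadings(R: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    Rr = R - np.diag(psi)
    eigvals, eigvecs = np.linalg.eigh(Rr)
    idx = np.argsort(eigvals)[::-1][:k]
    lam = np.sqrt(np.maximum(eigvals[idx], 0.0))
    return eigvecs[:, idx] * lam[None, :]


def _minres_objective(psi: np.ndarray, R: np.ndarray, k: int) -> float:
    L = _minres_loadings(R, psi, k)
    resid = R - L @ L.T
    np.fill_diagonal(resid, 0.0)
    return float(np.sum(resid**2) / 2.0)


def minres_extract(
    R: np.ndarray, n_factors: int, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Unrotated minres loadings and uniquenesses for a correlation matrix."""
    p = R.shape[0]
    if not 1 <= n_factors < p:
        raise ValueError("n_factors must be in [1, p)")
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    psi0 = np.clip(1.0 - smc, 0.02, 0.98)
    res = optimize.minimize(
        _minres_objective,
        psi0,
        args=(R, n_factors),
        method="L-BFGS-B",
        bounds=[(0.005, 1.0)] * p,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9},
    )
    if not res.success and res.status not in (1,):  # 1 = maxiter-ish soft stop
        raise RuntimeError(f"minres did not converge: {res.message}")
    psi = res.x
    return _minres_loadings(R, psi, n_factors), psi


# ---------------------------------------------------------------------------
# Oblimin rotation (gradient projection for oblique rotation)


def _oblimin_criterion(L: np.ndarray, gamma: float) -> tuple[float, np.ndarray]:
    p, k = L.shape
    L2 = L**2
    N = np.ones((k, k)) - np.eye(k)
    if gamma != 0.0:
        C = np.eye(p) - np.full((p, p), gamma / p)
        M = C @ L2 @ N
    else:
        M = L2 @ N
    f = float(np.sum(L2 * M) / 4.0)
    G = L * M
    return f, G


def oblimin_rotate(
    A: np.ndarray,
    gamma: float = 0.0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Oblique gradient-projection rotation with the oblimin criterion.

    gamma=0 is direct quartimin. Returns the rotated pattern matrix and the
    factor correlation matrix Phi.
    """
    p, k = A.shape
    if k == 1:
        return A.copy(), np.ones((1, 1))
    T = np.eye(k)
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _oblimin_criterion(L, gamma)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = np.linalg.norm(Gp)
        if s < tol:
            break
        al *= 2.0
        for _ in range(20):
            X = T - al * Gp
            v = 1.0 / np.sqrt(np.sum(X**2, axis=0))
            Tt = X * v[None, :]
            Ti = np.linalg.inv(Tt)
            L = A @ Ti.T
            ft, Gq = _oblimin_criterion(L, gamma)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T = Tt
        f = ft
        G = -(L.T @ Gq @ Ti).T
    Phi = T.T @ T
    return L, Phi


# ---------------------------------------------------------------------------
# Fitted model


@dataclass
class FactorModel:
    """Oblique factor solution over a feature set."""

    n_factors: int
    loadings: pd.DataFrame  # features x factors (pattern matrix)
    phi: np.ndarray  # factor correlations
    communalities: pd.Series
    uniquenesses: pd.Series
    rmsr: float  # root mean squared off-diagonal residual
    feature_means: np.ndarray
    feature_sds: np.ndarray

    @property
    def feature_names(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def factor_names(self) -> list[str]:
        return list(self.loadings.columns)

    def reproduced_correlation(self) -> np.ndarray:
        L = self.loadings.to_numpy()
        Rhat = L @ self.phi @ L.T
        np.fill_diagonal(Rhat, 1.0)
        return Rhat


def fit_minres_oblimin(
    X: pd.DataFrame | np.ndarray,
    n_factors: int,
    gamma: float = 0.0,
    rotate: bool = True,
) -> FactorModel:
    """Minres extraction followed by oblimin rotation.

    Factors are ordered by explained variance (sum of squared pattern
    loadings) and sign-flipped so each factor's largest-|loading| entry is
    positive; Phi rows/columns are permuted and flipped consistently.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"x{i + 1}" for i in range(Xv.shape[1])]
    means = Xv.mean(axis=0)
    sds = Xv.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("zero-variance feature(s) in factor analysis input")
    R = np.corrcoef(Xv, rowvar=False)
    A, psi = minres_extract(R, n_factors)
    if rotate and n_factors > 1:
        L, Phi = oblimin_rotate(A, gamma=gamma)
    else:
        L, Phi = A.copy(), np.eye(n_factors)
    # order by explained variance, orient signs
    ss = np.sum(L**2, axis=0)
    order = np.argsort(ss)[::-1]
    L = L[:, order]
    Phi = Phi[np.ix_(order, order)]
    for j in range(n_factors):
        i_max = np.argmax(np.abs(L[:, j]))
        if L[i_max, j] < 0:
            L[:, j] = -L[:, j]
            Phi[j, :] = -Phi[j, :]
            Phi[:, j] = -Phi[:, j]
    np.fill_diagonal(Phi, 1.0)
    comm = np.sum((L @ Phi) * L, axis=1)
    resid = R - (L @ Phi @ L.T + np.diag(psi))
    np.fill_diagonal(resid, 0.0)
    p = R.shape[0]
    rmsr = float(np.sqrt(np.sum(resid**2) / (p * (p - 1))))
    factor_names = [f"F{j + 1}" for j in range(n_factors)]
    return FactorModel(
        n_factors=n_factors,
        loadings=pd.DataFrame(L, index=names, columns=factor_names),
        phi=Phi,
        communalities=pd.Series(np.clip(comm, 0.0, 1.0), index=names),
        uniquenesses=pd.Series(psi, index=names),
        rmsr=rmsr,
        feature_means=means,
        feature_sds=sds,
    )


def factor_scores(
    model: FactorModel, X: pd.DataFrame | np.ndarray, method: str = "regression"
) -> pd.DataFrame:
    """Regression (Thurstone) factor scores: Z R^{-1} (Lambda Phi)."""
    if method != "regression":
        raise ValueError("only regression scores are implemented")
    if isinstance(X, pd.DataFrame):
        Xv = X[model.feature_names].to_numpy(dtype=float)
        index = X.index
    else:
        Xv = np.asarray(X, dtype=float)
        index = pd.RangeIndex(Xv.shape[0])
    Z = (Xv - model.feature_means) / model.feature_sds
    R = model.reproduced_correlation()
    # score on the observed correlation of the scoring features when possible
    R_obs = np.corrcoef(Z, rowvar=False) if Z.shape[0] > Z.shape[1] else R
    S = model.loadings.to_numpy() @ model.phi  # structure matrix
    try:
        W = np.linalg.solve(R_obs, S)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular correlation matrix; ridge-stabilized inverse used")
        W = np.linalg.solve(R_obs + 1e-6 * np.eye(R_obs.shape[0]), S)
    scores = Z @ W
    return pd.DataFrame(scores, index=index, columns=model.factor_names)
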