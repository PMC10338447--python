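"""Gaussian graphical model estimation by unregularized model selection.

Edges of the network are partial correlations: with precision matrix K,
w_ij = -K_ij / sqrt(K_ii K_jj), so a missing edge means conditional
independence given all remaining variables. Because the target regime has
n >> p, estimation is unregularized: a graphical-lasso path only seeds the
search, every candidate structure is refitted by constrained maximum
likelihood (K_ij = 0 enforced off-structure), and structures are compared by
the extended BIC

    EBIC = -2 loglik + |E| log n + 4 gamma |E| log p,

with gamma=0 reducing to the BIC. The search then greedily toggles single
edges (additions and removals each sweep, steepest-descent, lexicographic
tie-break) until no strictly improving change remains.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso


@dataclass(frozen=True)
class GgmConfig:
    ebic_gamma: float = 0.0
    glasso_path_length: int = 100
    glasso_path_ratio: float = 0.01  # smallest alpha relative to alpha_max
    convergence_tol: float = 1e-8
    max_sweeps: int = 200
    max_steps: int = 500  # cap on accepted stepwise changes

    def __post_init__(self) -> None:
        if self.ebic_gamma < 0:
            raise ValueError("ebic_gamma must be nonnegative")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")


@dataclass
class Network:
    """Partial-correlation network over factors and outcomes."""

    nodes: list[str]
    weights: np.ndarray  # symmetric, zero diagonal
    structure: np.ndarray  # boolean adjacency
    ebic: float
    n: int

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.structure, 1).sum())

    def edge_list(self) -> pd.DataFrame:
        rows = []
        p = len(self.nodes)
        for i in range(p):
            for j in range(i + 1, p):
                if self.structure[i, j]:
                    rows.append((self.nodes[i], self.nodes[j], self.weights[i, j]))
        return pd.DataFrame(rows, columns=["node1", "node2", "weight"])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, row in self.edge_list().iterrows():
            g.add_edge(row["node1"], row["node2"], weight=float(row["weight"]))
        return g

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "nodes": self.nodes,
                    "weights": self.weights.tolist(),
                    "ebic": self.ebic,
                    "n": self.n,
                },
                fh,
            )


def partial_correlations(precision: np.ndarray) -> np.ndarray:
    """Partial correlations from a symmetric positive-definite precision."""
    K = np.asarray(precision, dtype=float)
    if K.shape[0] != K.shape[1] or not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("precision must be symmetric")
    try:
        np.linalg.cholesky(K)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision must be positive definite") from exc
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return W


def _loglik(S: np.ndarray, K: np.ndarray, n: int) -> float:
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - float(np.sum(S * K)))


def fit_constrained_ml(
    S: np.ndarray,
    structure: np.ndarray,
    config: GgmConfig = GgmConfig(),
    n: int = 1,
    W0: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Maximum-likelihood precision with zeros enforced off-structure.

    Classical iterative conditional fitting over the covariance matrix: for
    each variable, the covariances to its non-neighbors are set so the
    implied precision entries vanish, sweeping until the working covariance
    stabilizes. The saturated structure returns S^{-1} exactly and the empty
    structure the diagonal 1/S_ii. Returns (precision, log-likelihood at
    sample size ``n``).
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    A = np.asarray(structure, dtype=bool).copy()
    np.fill_diagonal(A, False)
    if not np.array_equal(A, A.T):
        raise ValueError("structure must be symmetric")
    off = ~np.eye(p, dtype=bool)
    if A[off].all():  # saturated: unconstrained ML
        K = np.linalg.inv(S)
        K = 0.5 * (K + K.T)
        return K, _loglik(S, K, n)
    if not A.any():  # empty: independent variables
        K = np.diag(1.0 / np.diag(S))
        return K, _loglik(S, K, n)

    W = S.copy() if W0 is None else W0.copy()
    tol = config.convergence_tol * np.mean(np.abs(S[off])) if np.any(S[off]) else config.convergence_tol
    solve = np.linalg.solve
    neighbors = [np.flatnonzero(A[:, j]) for j in range(p)]
    others_idx = [np.concatenate([np.arange(j), np.arange(j + 1, p)]) for j in range(p)]
    for _ in range(config.max_sweeps):
        max_delta = 0.0
        for j in range(p):
            nb = neighbors[j]
            others = others_idx[j]
            w12_old = W[others, j]
            if nb.size == 0:
                w12_new = np.zeros(others.size)
            else:
                W11 = W[nb[:, None], nb]
                s12 = S[nb, j]
                beta = solve(W11, s12)
                w12_new = W[others[:, None], nb] @ beta
            delta = np.max(np.abs(w12_new - w12_old)) if others.size else 0.0
            if delta > max_delta:
                max_delta = delta
            W[others, j] = w12_new
            W[j, others] = w12_new
        if max_delta < tol:
            break
    else:
        raise RuntimeError("constrained ML did not converge within max_sweeps")

    # recover the precision from the final covariance sweeps
    K = np.zeros((p, p))
    for j in range(p):
        nb = neighbors[j]
        if nb.size == 0:
            K[j, j] = 1.0 / S[j, j]
            continue
        W11 = W[nb[:, None], nb]
        s12 = S[nb, j]
        beta = solve(W11, s12)
        k_jj = 1.0 / (S[j, j] - float(s12 @ beta))
        K[j, j] = k_jj
        K[nb, j] = -beta * k_jj
    K = 0.5 * (K + K.T)
    K[~A & off] = 0.0
    return K, _loglik(S, K, n)


def ebic(loglik: float, n: int, n_edges: int, p: int, gamma: float) -> float:
    """Extended BIC for a GGM structure (gamma=0 gives the BIC)."""
    if n < 1 or p < 1:
        raise ValueError("n and p must be at least 1")
    return -2.0 * loglik + n_edges * np.log(n) + 4.0 * gamma * n_edges * np.log(p)


def _score_structure(
    S: np.ndarray, A: np.ndarray, n: int, config: GgmConfig, W0=None
) -> tuple[float, np.ndarray]:
    K, ll = fit_constrained_ml(S, A, config, n=n, W0=W0)
    n_edges = int(np.triu(A, 1).sum())
    return ebic(ll, n, n_edges, S.shape[0], config.ebic_gamma), K


def _glasso_seed_structures(S: np.ndarray, config: GgmConfig) -> list[np.ndarray]:
    p = S.shape[0]
    off = np.abs(S - np.eye(p))
    alpha_max = off.max()
    if alpha_max <= 0:
        return [np.zeros((p, p), dtype=bool)]
    alphas = np.geomspace(
        alpha_max, alpha_max * config.glasso_path_ratio, config.glasso_path_length
    )
    structures: list[np.ndarray] = [np.zeros((p, p), dtype=bool)]
    seen = {structures[0].tobytes()}
    for alpha in alphas:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cov, prec = graphical_lasso(S, alpha=float(alpha), max_iter=200)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            continue
        A = np.abs(prec) > 1e-8
        np.fill_diagonal(A, False)
        A = A | A.T
        key = A.tobytes()
        if key not in seen:
            seen.add(key)
            structures.append(A)
    return structures


def ggm_mod_select(
    X: np.ndarray | pd.DataFrame,
    config: GgmConfig = GgmConfig(),
    nodes: list[str] | None = None,
) -> Network:
    """Unregularized GGM selection: glasso-seeded EBIC stepwise search.

    (i) a graphical-lasso path proposes candidate structures, each refitted
    by constrained ML and scored with EBIC; (ii) starting from the best seed,
    every single-edge addition and removal is evaluated per sweep and the
    best strictly-improving change accepted, to a local EBIC optimum.
    """
    if isinstance(X, pd.DataFrame):
        if nodes is None:
            nodes = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if nodes is None:
        nodes = [f"v{i + 1}" for i in range(p)]
    if n <= p:
        raise ValueError("need more observations than nodes for unregularized ML")
    if np.isnan(X).any():
        raise ValueError("input must be complete (no missing values)")
    S = np.corrcoef(X, rowvar=False)

    best_A, best_score, best_K = None, np.inf, None
    for A in _glasso_seed_structures(S, config):
        try:
            score, K = _score_structure(S, A, n, config)
        except (RuntimeError, np.linalg.LinAlgError):
            continue
        if score < best_score:
            best_A, best_score, best_K = A, score, K
    if best_A is None:
        raise RuntimeError("no seed structure could be fitted")

    pairs = list(itertools.combinations(range(p), 2))
    for _ in range(config.max_steps):
        cand_best = None  # (score, i, j, K)
        # warm-start candidate refits from the current model's covariance
        W_warm = np.linalg.inv(_spd_guard(best_K))
        for i, j in pairs:
            A_try = best_A.copy()
            A_try[i, j] = A_try[j, i] = not A_try[i, j]
            try:
                score, K = _score_structure(S, A_try, n, config, W0=W_warm)
            except (RuntimeError, np.linalg.LinAlgError):
                continue
            if score < best_score - 1e-10 and (
                cand_best is None or score < cand_best[0] - 1e-10
            ):
                cand_best = (score, i, j, K)
        if cand_best is None:
            break
        score, i, j, K = cand_best
        best_A = best_A.copy()
        best_A[i, j] = best_A[j, i] = not best_A[i, j]
        best_score, best_K = score, K
    else:
        warnings.warn("stepwise search hit the step cap; returning best-so-far")

    weights = partial_correlations(_spd_guard(best_K))
    weights[~best_A] = 0.0
    return Network(nodes=nodes, weights=weights, structure=best_A, ebic=float(best_score), n=n)


def _spd_guard(K: np.ndarray) -> np.ndarray:
    """Nudge a numerically near-SPD precision onto the SPD cone."""
    K = 0.5 * (K + K.T)
    try:
        np.linalg.cholesky(K)
        return K
    except np.linalg.LinAlgError:
        eigvals = np.linalg.eigvalsh(K)
        return K + (abs(eigvals.min()) + 1e-10) * np.eye(K.shape[0])


@dataclass
class FlowDiagram:
    """Two-layer neighborhood view of a network from a source node."""

    source: str
    layer1: list[tuple[str, float]]
    layer2: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    isolated: list[str] = field(default_factory=list)


def flow_from(net: Network, source: str) -> FlowDiagram:
    """Neighbors of the source, then how the rest connects to those neighbors."""
    if source not in net.nodes:
        raise ValueError(f"unknown node {source!r}")
    idx = {name: i for i, name in enumerate(net.nodes)}
    s = idx[source]
    layer1 = [
        (name, float(net.weights[s, idx[name]]))
        for name in net.nodes
        if name != source and net.structure[s, idx[name]]
    ]
    layer1_names = {name for name, _ in layer1}
    layer2: dict[str, list[tuple[str, float]]] = {}
    isolated: list[str] = []
    for name in net.nodes:
        if name == source or name in layer1_names:
            continue
        i = idx[name]
        links = [
            (l1, float(net.weights[i, idx[l1]]))
            for l1 in layer1_names
            if net.structure[i, idx[l1]]
        ]
        if links:
            layer2[name] = sorted(links)
        elif not net.structure[i].any():
            isolated.append(name)
        else:
            layer2[name] = []
    return FlowDiagram(source=source, layer1=sorted(layer1), layer2=layer2, isolated=isolated)
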