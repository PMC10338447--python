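"""Network robustness: edge bootstraps, case-drop centrality stability.

Three tools: (1) expected-influence centrality, the signed sum of each node's
edge weights; (2) nonparametric bootstrap of edge weights — resample rows
with replacement, refit the full model-selection pipeline, percentile CIs per
edge (an edge absent from a resample contributes weight zero); (3) case-drop
bootstrap for the CS coefficient — at each drop proportion d, subsample
(1-d)·n rows without replacement, refit, and correlate subsample expected
influence with the full-sample values; CS is the largest d at which at least
95% of those correlations stay >= 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ggm import GgmConfig, Network, ggm_mod_select

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))


@dataclass
class CentralityReport:
    """Expected influence per node."""

    expected_influence: pd.Series

    def top(self, k: int = 5) -> pd.Series:
        return self.expected_influence.sort_values(ascending=False).head(k)


def expected_influence(net: Network) -> CentralityReport:
    """One-step signed strength: EI_i = sum_j w_ij."""
    ei = net.weights.sum(axis=1)
    return CentralityReport(pd.Series(ei, index=net.nodes, name="expected_influence"))


@dataclass
class EdgeCIReport:
    """Per-edge bootstrap summary (percentile CIs)."""

    table: pd.DataFrame  # node1, node2, sample, boot_mean, ci_low, ci_high, stable
    n_boot: int
    n_skipped: int

    def stable_edges(self) -> pd.DataFrame:
        return self.table[self.table["stable"]]

    def outcome_edges(self, outcome_nodes: list[str]) -> pd.DataFrame:
        """Table-2-shaped summary for edges incident to the outcome nodes."""
        mask = self.table["node1"].isin(outcome_nodes) | self.table["node2"].isin(
            outcome_nodes
        )
        out = self.table[mask].copy()
        out["bootstrapped_95_ci"] = out.apply(
            lambda r: f"{r.ci_low:.3f}, {r.ci_high:.3f}", axis=1
        )
        return out[["node1", "node2", "sample", "boot_mean", "bootstrapped_95_ci"]]


def _weights_of(net: Network) -> np.ndarray:
    return net.weights


def bootstrap_edges(
    X: np.ndarray | pd.DataFrame,
    config: GgmConfig = GgmConfig(),
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    nodes: list[str] | None = None,
    sample_network: Network | None = None,
) -> EdgeCIReport:
    """Nonparametric bootstrap of edge weights with full model refits."""
    if isinstance(X, pd.DataFrame):
        if nodes is None:
            nodes = list(X.columns)
        X = X.to_numpy(dtype=float)
    n, p = X.shape
    if nodes is None:
        nodes = [f"v{i + 1}" for i in range(p)]
    if sample_network is None:
        sample_network = ggm_mod_select(X, config, nodes=nodes)
    rng = np.random.default_rng(seed)
    boots = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            net_b = ggm_mod_select(X[idx], config, nodes=nodes)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            skipped += 1
            continue
        boots.append(net_b.weights)
    if n_boot > 0 and skipped > 0.10 * n_boot:
        raise RuntimeError(f"{skipped}/{n_boot} bootstrap refits failed")
    stack = np.stack(boots) if boots else np.zeros((0, p, p))
    lo_q = 100 * (1 - ci_level) / 2
    hi_q = 100 - lo_q
    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            draws = stack[:, i, j] if stack.shape[0] else np.array([0.0])
            lo, hi = np.percentile(draws, [lo_q, hi_q])
            mean = float(draws.mean())
            rows.append(
                {
                    "node1": nodes[i],
                    "node2": nodes[j],
                    "sample": float(sample_network.weights[i, j]),
                    "boot_mean": mean,
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "stable": bool(lo > 0 or hi < 0),
                }
            )
    return EdgeCIReport(pd.DataFrame(rows), n_boot=len(boots), n_skipped=skipped)


@dataclass
class CsReport:
    """Case-drop bootstrap summary for centrality stability."""

    drop_grid: list[float]
    correlations: dict[float, np.ndarray] = field(repr=False, default_factory=dict)
    cs_coefficient: float = 0.0
    correlation_threshold: float = 0.7
    certainty: float = 0.95

    def quantiles(self) -> pd.DataFrame:
        rows = []
        for d in self.drop_grid:
            c = self.correlations.get(d, np.array([]))
            if c.size == 0:
                continue
            rows.append(
                {
                    "drop": d,
                    "q05": float(np.quantile(c, 0.05)),
                    "median": float(np.median(c)),
                    "q95": float(np.quantile(c, 0.95)),
                }
            )
        return pd.DataFrame(rows)


def casedrop_cs(
    X: np.ndarray | pd.DataFrame,
    config: GgmConfig = GgmConfig(),
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID,
    n_boot_per_level: int = 50,
    seed: int = 0,
    correlation_threshold: float = 0.7,
    certainty: float = 0.95,
    nodes: list[str] | None = None,
) -> CsReport:
    """CS coefficient for expected-influence centrality.

    At each drop proportion the model is refitted on row subsamples drawn
    without replacement and the subsample expected influence is correlated
    (Pearson, across nodes) with the full-sample expected influence. The CS
    coefficient is the largest drop proportion at which the required
    certainty of exceeding the correlation threshold still holds, or 0.
    """
    if isinstance(X, pd.DataFrame):
        if nodes is None:
            nodes = list(X.columns)
        X = X.to_numpy(dtype=float)
    n, p = X.shape
    max_drop = max(drop_grid)
    if int(np.floor(n * (1 - max_drop))) <= p:
        raise ValueError("largest drop proportion leaves too few rows")
    full_net = ggm_mod_select(X, config, nodes=nodes)
    full_ei = expected_influence(full_net).expected_influence.to_numpy()
    rng = np.random.default_rng(seed)
    report = CsReport(
        drop_grid=sorted(drop_grid),
        correlation_threshold=correlation_threshold,
        certainty=certainty,
    )
    skipped_total = 0
    for d in report.drop_grid:
        m = int(np.floor(n * (1 - d)))
        corrs = []
        for _ in range(n_boot_per_level):
            idx = rng.choice(n, size=m, replace=False)
            try:
                net_b = ggm_mod_select(X[idx], config, nodes=nodes)
            except (RuntimeError, ValueError, np.linalg.LinAlgError):
                skipped_total += 1
                continue
            ei_b = expected_influence(net_b).expected_influence.to_numpy()
            if np.std(ei_b) == 0 or np.std(full_ei) == 0:
                corrs.append(0.0)
            else:
                corrs.append(float(np.corrcoef(full_ei, ei_b)[0, 1]))
        report.correlations[d] = np.asarray(corrs)
    total = n_boot_per_level * len(report.drop_grid)
    if skipped_total > 0.10 * total:
        raise RuntimeError(f"{skipped_total}/{total} case-drop refits failed")
    cs = 0.0
    for d in report.drop_grid:
        c = report.correlations[d]
        if c.size and np.mean(c >= correlation_threshold) >= certainty:
            cs = d
    report.cs_coefficient = cs
    return report
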