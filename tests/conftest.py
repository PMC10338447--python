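"""Shared fixtures: small synthetic cohorts and benchmark networks."""

from __future__ import annotations

import numpy as np
import pytest

from aggnet import synthetic as syn


@pytest.fixture(scope="session")
def small_config() -> syn.SyntheticConfig:
    """A cohort small enough for fast tests but structurally complete."""
    return syn.SyntheticConfig(
        n_participants=700,
        n_scales=8,
        items_per_scale=8,
        n_items_total=64,
        n_latent_factors=6,
        n_outcome_factors=3,
        n_nominal_items=4,
        n_string_items=2,
        n_high_missing_items=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return syn.generate_cohort(small_config)


def sparse_benchmark(p: int = 15, seed: int = 0, w: float = 0.25, n_extra: int = 4):
    """A sparse precision matrix (chain plus a few long-range edges).

    Returns (correlation_matrix, true_structure) with partial correlations of
    magnitude roughly ``w``.
    """
    rng = np.random.default_rng(seed)
    K = np.eye(p)
    edges = [(i, i + 1) for i in range(p - 1)]
    while len(edges) < p - 1 + n_extra:
        i, j = sorted(rng.choice(p, 2, replace=False))
        if i != j and (i, j) not in edges:
            edges.append((i, j))
    for i, j in edges:
        K[i, j] = K[j, i] = -w * rng.choice([-1.0, 1.0])
    ev = np.linalg.eigvalsh(K)
    if ev.min() < 0.1:
        K += (0.15 - ev.min()) * np.eye(p)
    cov = np.linalg.inv(K)
    d = np.sqrt(np.diag(cov))
    cov = cov / np.outer(d, d)
    structure = np.zeros((p, p), dtype=bool)
    for i, j in edges:
        structure[i, j] = structure[j, i] = True
    return cov, structure


def sample_mvn(cov: np.ndarray, n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(np.zeros(cov.shape[0]), cov, size=n)
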