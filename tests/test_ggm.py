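"""Partial correlations, constrained ML, EBIC scoring, stepwise selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aggnet.ggm import (
    GgmConfig,
    ebic,
    fit_constrained_ml,
    flow_from,
    ggm_mod_select,
    partial_correlations,
    Network,
)
from conftest import sample_mvn, sparse_benchmark


def random_correlation(p: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((p, p + 3))
    S = A @ A.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


class TestPartialCorrelations:
    def test_two_by_two_by_hand(self):
        K = np.array([[2.0, -1.0], [-1.0, 2.0]])
        W = partial_correlations(K)
        assert W[0, 1] == pytest.approx(0.5)
        assert W[0, 0] == 0.0

    def test_diagonal_precision_gives_zero_weights(self):
        W = partial_correlations(np.diag([1.0, 2.0, 3.0]))
        assert np.abs(W).max() == 0.0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_recursive_three_variable_formula(self, seed):
        R = random_correlation(3, seed)
        K = np.linalg.inv(R)
        W = partial_correlations(K)
        r12, r13, r23 = R[0, 1], R[0, 2], R[1, 2]
        expected = (r12 - r13 * r23) / np.sqrt((1 - r13**2) * (1 - r23**2))
        assert W[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_non_spd_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            partial_correlations(bad)


class TestConstrainedML:
    def test_saturated_structure_equals_inverse(self):
        S = random_correlation(6, 1)
        K, _ = fit_constrained_ml(S, np.ones((6, 6), bool))
        np.testing.assert_allclose(K, np.linalg.inv(S), atol=1e-8)

    def test_empty_structure_is_diagonal(self):
        S = random_correlation(5, 2)
        K, _ = fit_constrained_ml(S, np.zeros((5, 5), bool))
        np.testing.assert_allclose(K, np.diag(1.0 / np.diag(S)), atol=1e-12)

    def test_ml_stationarity_on_edges(self):
        """At the ML solution, (K^{-1})_ij = S_ij on every edge and the diagonal."""
        S = random_correlation(7, 3)
        A = np.zeros((7, 7), bool)
        for i, j in [(0, 1), (1, 2), (2, 3), (0, 4), (5, 6)]:
            A[i, j] = A[j, i] = True
        K, _ = fit_constrained_ml(S, A)
        W = np.linalg.inv(K)
        np.testing.assert_allclose(np.diag(W), np.diag(S), atol=1e-6)
        np.testing.assert_allclose(W[A], S[A], atol=1e-6)
        off = ~np.eye(7, dtype=bool)
        assert np.abs(K[~A & off]).max() == 0.0

    def test_saturated_partials_match_classical_formula(self):
        S = random_correlation(5, 4)
        K, _ = fit_constrained_ml(S, np.ones((5, 5), bool))
        W = partial_correlations(K)
        Kinv = np.linalg.inv(S)
        d = np.sqrt(np.diag(Kinv))
        expected = -Kinv / np.outer(d, d)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(W, expected, atol=1e-8)


class TestEbic:
    def test_gamma_zero_reduces_to_bic(self):
        assert ebic(-100.0, 500, 4, 10, 0.0) == pytest.approx(
            200.0 + 4 * np.log(500)
        )

    def test_useless_edge_strictly_worsens_score(self):
        base = ebic(-50.0, 200, 3, 8, 0.5)
        assert ebic(-50.0, 200, 4, 8, 0.5) > base

    def test_ranking_matches_exhaustive_enumeration_small_case(self):
        """Stepwise result equals the EBIC argmin over all 64 structures, p=4."""
        rng = np.random.default_rng(0)
        K_true = np.array(
            [
                [1.0, -0.3, 0.0, 0.0],
                [-0.3, 1.0, -0.3, 0.0],
                [0.0, -0.3, 1.0, 0.0],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
        cov = np.linalg.inv(K_true)
        d = np.sqrt(np.diag(cov))
        cov /= np.outer(d, d)
        X = rng.multivariate_normal(np.zeros(4), cov, size=2000)
        S = np.corrcoef(X, rowvar=False)
        cfg = GgmConfig()
        best_score, best_A = np.inf, None
        pairs = list(itertools.combinations(range(4), 2))
        for bits in itertools.product([0, 1], repeat=6):
            A = np.zeros((4, 4), bool)
            for b, (i, j) in zip(bits, pairs):
                if b:
                    A[i, j] = A[j, i] = True
            K, ll = fit_constrained_ml(S, A, cfg, n=2000)
            score = ebic(ll, 2000, int(np.triu(A, 1).sum()), 4, cfg.ebic_gamma)
            if score < best_score:
                best_score, best_A = score, A
        net = ggm_mod_select(X, cfg)
        np.testing.assert_array_equal(net.structure, best_A)
        assert net.ebic == pytest.approx(best_score, abs=1e-6)


class TestModelSelection:
    def test_independent_variables_give_near_empty_network(self):
        spurious = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((5000, 8))
            net = ggm_mod_select(X)
            spurious.append(net.n_edges)
        assert np.median(spurious) <= 1

    def test_sparse_structure_recovery(self):
        cov, truth = sparse_benchmark(p=10, seed=1)
        X = sample_mvn(cov, 5000, seed=2)
        net = ggm_mod_select(X)
        iu = np.triu_indices(10, 1)
        tp = (net.structure & truth)[iu].sum()
        fn = (~net.structure & truth)[iu].sum()
        fp = (net.structure & ~truth)[iu].sum()
        tn = (~net.structure & ~truth)[iu].sum()
        assert tp / (tp + fn) >= 0.9
        assert tn / (tn + fp) >= 0.9

    def test_final_ebic_not_worse_than_seed(self):
        # the stepwise phase only accepts strict improvements, so the final
        # score can never exceed any seed structure's score
        cov, _ = sparse_benchmark(p=8, seed=3)
        X = sample_mvn(cov, 2000, seed=4)
        S = np.corrcoef(X, rowvar=False)
        cfg = GgmConfig()
        net = ggm_mod_select(X, cfg)
        K_emp, ll_emp = fit_constrained_ml(S, np.zeros((8, 8), bool), cfg, n=2000)
        assert net.ebic <= ebic(ll_emp, 2000, 0, 8, 0.0) + 1e-9

    def test_n_not_greater_than_p_rejected(self):
        with pytest.raises(ValueError):
            ggm_mod_select(np.zeros((5, 6)))

    def test_estimated_weights_approach_true_partials(self):
        cov, truth = sparse_benchmark(p=10, seed=5)
        X = sample_mvn(cov, 20000, seed=6)
        net = ggm_mod_select(X)
        K_true = np.linalg.inv(cov)
        W_true = partial_correlations(K_true)
        err = np.abs(net.weights - W_true)[truth]
        assert err.max() < 0.05


class TestFlow:
    def _net(self, weights, nodes):
        W = np.asarray(weights, float)
        return Network(
            nodes=nodes, weights=W, structure=W != 0, ebic=0.0, n=100
        )

    def test_star_graph_puts_all_nodes_in_layer_one(self):
        W = np.zeros((4, 4))
        for j in (1, 2, 3):
            W[0, j] = W[j, 0] = 0.2
        flow = flow_from(self._net(W, list("abcd")), "a")
        assert [n for n, _ in flow.layer1] == ["b", "c", "d"]
        assert flow.layer2 == {}

    def test_isolated_source_has_empty_layer_one(self):
        W = np.zeros((3, 3))
        W[1, 2] = W[2, 1] = 0.4
        flow = flow_from(self._net(W, list("abc")), "a")
        assert flow.layer1 == []

    def test_path_graph_layers(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.3
        W[1, 2] = W[2, 1] = 0.5
        flow = flow_from(self._net(W, list("abc")), "a")
        assert flow.layer1 == [("b", pytest.approx(0.3))]
        assert flow.layer2 == {"c": [("b", pytest.approx(0.5))]}

    def test_unknown_source_rejected(self):
        W = np.zeros((2, 2))
        with pytest.raises(ValueError):
            flow_from(self._net(W, list("ab")), "zzz")
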