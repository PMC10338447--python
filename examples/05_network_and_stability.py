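"""Estimate a partial-correlation network and quantify its robustness.

The Gaussian graphical model is selected without regularization: a
graphical-lasso path seeds candidate structures, each refitted by
constrained maximum likelihood and scored by EBIC, then single edges are
added/removed until no change improves the score. Stability: nonparametric
bootstrap CIs for edge weights, and the case-drop CS coefficient for
expected-influence centrality (the largest fraction of participants that can
be dropped while subset and full-sample centralities still correlate >= 0.7
with 95% certainty).
"""

import numpy as np

from aggnet import GgmConfig, bootstrap_edges, casedrop_cs, expected_influence, flow_from, ggm_mod_select

rng = np.random.default_rng(2)
p, n = 10, 4000
K = np.eye(p)
for i in range(p - 1):
    K[i, i + 1] = K[i + 1, i] = -0.3
K[0, 5] = K[5, 0] = 0.25
ev = np.linalg.eigvalsh(K)
K += (0.15 - min(ev.min(), 0.0)) * np.eye(p)
cov = np.linalg.inv(K)
d = np.sqrt(np.diag(cov))
cov /= np.outer(d, d)
X = rng.multivariate_normal(np.zeros(p), cov, size=n)
nodes = [f"F{i + 1}" for i in range(p - 2)] + ["GPsy", "Aggr"]

config = GgmConfig(glasso_path_length=30)
net = ggm_mod_select(X, config, nodes=nodes)
print(f"selected {net.n_edges} edges (EBIC {net.ebic:.1f})")
print(net.edge_list().round(3).to_string(index=False))

ei = expected_influence(net)
print(f"\nexpected influence (signed strength):\n{ei.expected_influence.round(3).to_string()}")

flow = flow_from(net, "GPsy")
print(f"\nflow from GPsy -> direct neighbors: {[(a, round(w, 3)) for a, w in flow.layer1]}")

boot = bootstrap_edges(X, config, n_boot=50, seed=3, nodes=nodes, sample_network=net)
stable = boot.stable_edges()
print(f"\n{len(stable)} of {len(boot.table)} edges have bootstrap CIs excluding zero")

cs = casedrop_cs(X, config, n_boot_per_level=8, seed=4, nodes=nodes)
print(f"CS coefficient: {cs.cs_coefficient:.2f} "
      "(fraction of cases droppable while centrality stays correlated >= 0.7)")
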