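import numpy as np
import pandas as pd
import pytest

from asymstroke.network import (
    GaussianGraph,
    bn_score,
    bootstrap_arcs,
    centrality,
    correlation_matrix,
    glasso_network,
    hill_climb_bn,
    noa,
)


def chain_data(seed, n=1000, coef=0.4):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n)
    b = coef * a + rng.normal(size=n)
    c = coef * b + rng.normal(size=n)
    return np.column_stack([a, b, c])


class TestGlasso:
    def test_two_node_weight_approaches_marginal_correlation(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(5000, 2))
        x = z[:, 0]
        y = 0.6 * x + np.sqrt(1 - 0.36) * z[:, 1]
        g = glasso_network(np.column_stack([x, y]), lambdas=[1e-4],
                          method="pearson")
        assert g.weights[0, 1] == pytest.approx(0.6, abs=0.03)

    def test_matches_precision_inversion_at_small_lambda(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 6))
        cov = a @ a.T + 6 * np.eye(6)
        d = np.sqrt(np.diag(cov))
        x = rng.multivariate_normal(np.zeros(6), cov / np.outer(d, d), size=5000)
        g = glasso_network(x, lambdas=[1e-4], method="pearson")
        k = np.linalg.inv(np.corrcoef(x.T))
        dd = np.sqrt(np.diag(k))
        pc = -k / np.outer(dd, dd)
        np.fill_diagonal(pc, 0.0)
        assert np.max(np.abs(g.weights - pc)) < 0.02

    def test_chain_drops_indirect_edge(self):
        absent = sum(abs(glasso_network(chain_data(s), gamma=0.5,
                                        method="pearson").weights[0, 2]) < 1e-8
                     for s in range(20))
        assert absent >= 18

    def test_independent_columns_give_empty_graph(self):
        zero = sum(len(glasso_network(np.random.default_rng(s).normal(size=(500, 5)),
                                      gamma=0.5, method="pearson").edges()) == 0
                   for s in range(20))
        assert zero >= 18

    def test_edge_count_non_increasing_in_gamma(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(300, 6))
        x[:, 1] += 0.5 * x[:, 0]
        x[:, 2] += 0.4 * x[:, 1]
        counts = [len(glasso_network(x, gamma=g).edges()) for g in (0.0, 0.25, 0.5)]
        assert counts == sorted(counts, reverse=True)

    def test_weights_symmetric_and_bounded(self):
        g = glasso_network(chain_data(1), gamma=0.5)
        assert np.allclose(g.weights, g.weights.T)
        assert np.all(np.abs(g.weights) <= 1.0)
        assert np.all(np.diag(g.weights) == 0.0)

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError):
            glasso_network(np.random.default_rng(0).normal(size=(50, 1)))

    def test_spearman_sine_mapping(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4000, 2))
        x[:, 1] = 0.5 * x[:, 0] + np.sqrt(0.75) * x[:, 1]
        corr = correlation_matrix(x, method="spearman")
        assert corr[0, 1] == pytest.approx(0.5, abs=0.05)


class TestCentrality:
    def _graph(self, weights, nodes=None):
        w = np.asarray(weights, dtype=float)
        nodes = nodes or [f"n{i}" for i in range(w.shape[0])]
        return GaussianGraph(nodes, w, 0.1, 0.5, 100)

    def test_toy_three_node_path(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.3
        t = centrality(self._graph(w)).set_index("node")
        assert t.loc["n1", "strength"] == pytest.approx(0.8)
        assert t.loc["n1", "expected_influence"] == pytest.approx(0.8)
        assert t.loc["n1", "betweenness"] == pytest.approx(1.0)
        assert t.loc["n0", "betweenness"] == 0.0

    def test_signed_weights_split_strength_and_influence(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = -0.5
        w[1, 2] = w[2, 1] = 0.3
        t = centrality(self._graph(w)).set_index("node")
        assert t.loc["n1", "strength"] == pytest.approx(0.8)
        assert t.loc["n1", "expected_influence"] == pytest.approx(-0.2)

    def test_empty_graph_all_zero(self):
        t = centrality(self._graph(np.zeros((4, 4))))
        assert (t[["strength", "closeness", "betweenness",
                   "expected_influence"]] == 0).all().all()

    def test_strength_bounds_expected_influence(self):
        g = glasso_network(chain_data(5), gamma=0.0)
        t = centrality(g)
        assert np.all(t.strength + 1e-12 >= np.abs(t.expected_influence))


class TestHillClimb:
    def test_independent_columns_give_empty_dag(self):
        # BIC arc-inclusion threshold sits near the 95th percentile of the
        # max spurious correlation, so ~95% of null datasets stay empty
        empty = sum(len(hill_climb_bn(np.random.default_rng(s).normal(size=(1000, 4)),
                                      seed=s).arcs) == 0
                    for s in range(30))
        assert empty >= 26

    def test_collider_recovered_with_restarts(self):
        ok = 0
        for s in range(15):
            rng = np.random.default_rng(s)
            a = rng.normal(size=2000)
            b = rng.normal(size=2000)
            c = a + b + rng.normal(size=2000)
            fit = hill_climb_bn(np.column_stack([a, b, c]), restarts=3, seed=s)
            ok += set(fit.arcs) == {("x0", "x2"), ("x1", "x2")}
        assert ok >= 13

    def test_score_self_consistency(self):
        x = chain_data(2)
        fit = hill_climb_bn(x, seed=0)
        assert fit.score == pytest.approx(bn_score(x, fit.arcs))

    def test_always_acyclic(self):
        import networkx as nx

        for s in range(10):
            rng = np.random.default_rng(s)
            x = rng.normal(size=(200, 5))
            x[:, 1] += x[:, 0]
            x[:, 3] += 0.5 * x[:, 2] + 0.3 * x[:, 1]
            fit = hill_climb_bn(x, restarts=1, seed=s)
            g = nx.DiGraph(fit.arcs)
            g.add_nodes_from(fit.nodes)
            assert nx.is_directed_acyclic_graph(g)


class TestBootstrapArcs:
    def test_single_bootstrap_gives_binary_strengths(self):
        res = bootstrap_arcs(chain_data(0, n=300), n_boot=1, seed=0)
        assert all(v in (0.0, 1.0) for v in res.strengths.values())

    def test_deterministic_per_seed(self):
        x = chain_data(1, n=300)
        r1 = bootstrap_arcs(x, n_boot=25, seed=5)
        r2 = bootstrap_arcs(x, n_boot=25, seed=5)
        assert r1.strengths == r2.strengths
        assert r1.arcs == r2.arcs

    def test_collider_consensus(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=2000)
        b = rng.normal(size=2000)
        c = a + b + rng.normal(size=2000)
        res = bootstrap_arcs(np.column_stack([a, b, c]), n_boot=100, seed=1,
                             restarts=2)
        assert ("x0", "x2") in res.arcs and ("x1", "x2") in res.arcs
        assert res.direction_probs[("x0", "x2")] >= 0.51
        assert res.direction_probs[("x1", "x2")] >= 0.51

    def test_invalid_parameters(self):
        x = chain_data(0, n=100)
        with pytest.raises(ValueError):
            bootstrap_arcs(x, n_boot=0)
        with pytest.raises(ValueError):
            bootstrap_arcs(x, n_boot=10, direction_threshold=0.4)


class TestNoa:
    def test_consistency_with_glasso_on_same_columns(self):
        df = pd.DataFrame(chain_data(4), columns=["a", "b", "c"])
        g_direct = glasso_network(df[["a", "b", "c"]], gamma=0.5)
        g_noa, cent, nb = noa(df, ["a", "b"], "c", gamma=0.5)
        assert np.allclose(g_noa.weights, g_direct.weights)
        assert list(cent.node) == ["a", "b", "c"]

    def test_independent_outcome_has_no_neighbours(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            df = pd.DataFrame({f"b{i}": rng.normal(size=500) for i in range(4)})
            df["out"] = rng.normal(size=500)
            _, _, nb = noa(df, [f"b{i}" for i in range(4)], "out",
                           method="pearson")
            hits += len(nb) == 0
        assert hits >= 9

    def test_outcome_in_baselines_rejected(self):
        df = pd.DataFrame(chain_data(0), columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            noa(df, ["a", "c"], "c")

    def test_missing_variable_rejected(self):
        df = pd.DataFrame(chain_data(0), columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="not in data"):
            noa(df, ["a", "zzz"], "c")
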