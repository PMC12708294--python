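"""Partial-correlation (graphical lasso) and score-based directed networks.

The undirected network is an L1-penalized Gaussian precision estimate with
the penalty chosen by minimum EBIC; edge weights are the partial
correlations ``-k_ij / sqrt(k_ii k_jj)`` and no further edge threshold is
applied.  Input correlations default to Spearman rank correlations mapped
through ``2 sin(pi rho / 6)`` onto the Pearson scale, which is more robust
for ordinal scale scores; plain Pearson is available by flag.

The directed network is greedy hill climbing over single-arc additions,
deletions and reversals maximising the Gaussian BIC, with ties between
equally scoring moves broken at random (so score-equivalent orientations
are sampled evenly across bootstrap refits).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.covariance import graphical_lasso as _sk_glasso

__all__ = [
    "GaussianGraph",
    "DirectedGraph",
    "correlation_matrix",
    "glasso_network",
    "centrality",
    "hill_climb_bn",
    "bn_score",
    "bootstrap_arcs",
    "noa",
]


@dataclass
class GaussianGraph:
    nodes: list[str]
    weights: np.ndarray  # symmetric, zero diagonal, partial correlations
    lam: float
    gamma: float
    n: int

    def edges(self, tol: float = 1e-8):
        p = len(self.nodes)
        return [(self.nodes[i], self.nodes[j], float(self.weights[i, j]))
                for i in range(p) for j in range(i + 1, p)
                if abs(self.weights[i, j]) > tol]


@dataclass
class DirectedGraph:
    nodes: list[str]
    arcs: list[tuple[str, str]]
    score: float = float("nan")
    strengths: dict = field(default_factory=dict)       # frozenset pair -> fraction
    direction_probs: dict = field(default_factory=dict)  # (u, v) -> fraction
    undirected: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Graphical lasso with EBIC selection
# ---------------------------------------------------------------------------


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    arr = np.asarray(data, dtype=float)
    return pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])


def correlation_matrix(data, method: str = "spearman") -> np.ndarray:
    """Correlation matrix; Spearman values are mapped onto the Pearson scale."""
    df = _as_frame(data)
    if method == "pearson":
        corr = df.corr(method="pearson").to_numpy()
    elif method == "spearman":
        rho = df.corr(method="spearman").to_numpy()
        corr = 2.0 * np.sin(np.pi * rho / 6.0)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    np.fill_diagonal(corr, 1.0)
    # guarantee positive definiteness for the glasso solver
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() < 1e-4:
        eigval = np.clip(eigval, 1e-4, None)
        corr = eigvec @ np.diag(eigval) @ eigvec.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
    return corr


def _partial_correlations(precision: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(precision))
    w = -precision / np.outer(d, d)
    np.fill_diagonal(w, 0.0)
    return w


def _edge_count(precision: np.ndarray, tol: float = 1e-8) -> int:
    off = precision[np.triu_indices_from(precision, k=1)]
    return int(np.sum(np.abs(off) > tol))


def constrained_mle_precision(corr: np.ndarray, pattern: np.ndarray,
                              max_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Gaussian MLE precision restricted to a zero pattern.

    Coordinate updates over the covariance (Hastie's graphical-model MLE
    iteration): each variable's covariance row is the projection of its
    sample covariances onto its neighbour set.
    """
    p = corr.shape[0]
    w = corr.copy()
    others = [np.delete(np.arange(p), j) for j in range(p)]
    for _ in range(max_iter):
        w_old = w.copy()
        for j in range(p):
            idx = others[j]
            nb = idx[pattern[idx, j]]
            w12 = np.zeros(p - 1)
            if nb.size:
                pos = np.searchsorted(idx, nb)
                w11 = w[np.ix_(idx, idx)]
                beta = np.zeros(p - 1)
                beta[pos] = np.linalg.solve(w11[np.ix_(pos, pos)], corr[nb, j])
                w12 = w11 @ beta
            w[idx, j] = w12
            w[j, idx] = w12
        if np.max(np.abs(w - w_old)) < tol:
            break
    precision = np.linalg.inv(w)
    off = ~pattern & ~np.eye(p, dtype=bool)
    precision[off] = 0.0
    return precision


def ebic(precision: np.ndarray, corr: np.ndarray, n: int, gamma: float,
         refit: bool = True) -> float:
    """Extended BIC of a precision estimate.

    With ``refit`` (the default) the likelihood term is evaluated at the
    unpenalized MLE restricted to the estimate's zero pattern, so model
    comparison is not biased toward dense, lightly shrunken solutions.
    """
    p = corr.shape[0]
    e = _edge_count(precision)
    if refit:
        pattern = np.abs(precision) > 1e-8
        np.fill_diagonal(pattern, True)
        precision = constrained_mle_precision(corr, pattern)
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return float("inf")
    loglik = n / 2.0 * (logdet - float(np.sum(corr * precision)))
    return -2.0 * loglik + e * math.log(n) + 4.0 * e * gamma * math.log(p)


def glasso_network(data, gamma: float = 0.5, lambdas=None,
                   method: str = "spearman", n_lambda: int = 100,
                   lambda_min_ratio: float = 0.01) -> GaussianGraph:
    """EBIC-selected graphical-lasso partial-correlation network.

    All nonzero edges of the selected precision matrix are retained (no
    fixed weight threshold).
    """
    df = _as_frame(data).dropna()
    nodes = list(df.columns)
    n, p = df.shape
    if p < 2:
        raise ValueError("need at least 2 numeric columns")
    if n <= p:
        warnings.warn("fewer observations than variables; estimates unstable")
    corr = correlation_matrix(df, method=method)
    if lambdas is None:
        lam_max = float(np.max(np.abs(corr - np.eye(p))))
        lam_max = max(lam_max, 1e-4)
        # start strictly above lam_max so the empty graph is a real candidate
        # (at lam_max exactly the solver leaves numerical dust on the edges)
        lambdas = np.geomspace(lam_max * 1.05, lam_max * lambda_min_ratio, n_lambda)
    best = None
    score_cache: dict[bytes, float] = {}
    for lam in np.asarray(lambdas, dtype=float):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, precision = _sk_glasso(corr, alpha=float(lam), max_iter=200)
        except FloatingPointError:
            continue
        pattern_key = (np.abs(precision) > 1e-8).tobytes()
        if pattern_key not in score_cache:
            score_cache[pattern_key] = ebic(precision, corr, n, gamma)
        score = score_cache[pattern_key]
        if best is None or score < best[0]:
            best = (score, float(lam), precision)
    if best is None:
        raise ValueError("graphical lasso failed to converge on the whole grid; "
                         "input correlation matrix may be ill-conditioned")
    _, lam, precision = best
    weights = np.clip(_partial_correlations(precision), -1.0, 1.0)
    return GaussianGraph(nodes, weights, lam, gamma, n)


def centrality(graph: GaussianGraph, tol: float = 1e-8) -> pd.DataFrame:
    """Strength, closeness, betweenness and expected influence per node.

    Path-based indices use edge length ``1 / |weight|``; closeness is the
    reciprocal of the summed shortest-path lengths to all other nodes, with
    0 for nodes that cannot reach the whole graph.
    """
    p = len(graph.nodes)
    w = graph.weights
    strength = np.abs(w).sum(axis=1)
    expected_influence = w.sum(axis=1)

    g = nx.Graph()
    g.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if abs(w[i, j]) > tol:
                g.add_edge(i, j, length=1.0 / abs(w[i, j]))
    closeness = np.zeros(p)
    for i in range(p):
        if p == 1:
            break
        dist = nx.single_source_dijkstra_path_length(g, i, weight="length")
        if len(dist) == p:
            total = sum(v for k, v in dist.items() if k != i)
            closeness[i] = 1.0 / total if total > 0 else 0.0
    betweenness = np.zeros(p)
    if p > 2:
        bc = nx.betweenness_centrality(g, weight="length", normalized=False)
        for i, v in bc.items():
            betweenness[i] = v
    return pd.DataFrame({
        "node": graph.nodes,
        "strength": strength,
        "closeness": closeness,
        "betweenness": betweenness,
        "expected_influence": expected_influence,
    })


# ---------------------------------------------------------------------------
# Score-based directed network (hill climbing, Gaussian BIC)
# ---------------------------------------------------------------------------


def _node_loglik(x: np.ndarray, child: int, parents: tuple[int, ...]) -> float:
    n = x.shape[0]
    y = x[:, child]
    if parents:
        design = np.column_stack([np.ones(n), x[:, list(parents)]])
        resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        sigma2 = float(resid @ resid) / n
    else:
        sigma2 = float(np.var(y))
    sigma2 = max(sigma2, 1e-12)
    return -n / 2.0 * (math.log(2.0 * math.pi * sigma2) + 1.0)


def _node_score(x, child, parents, n) -> float:
    # parameters: |parents| coefficients + intercept + residual variance
    penalty = (len(parents) + 2) / 2.0 * math.log(n)
    return _node_loglik(x, child, parents) - penalty


def bn_score(data, arcs) -> float:
    """Gaussian BIC of a directed structure (independent re-scoring path)."""
    df = _as_frame(data).dropna()
    nodes = list(df.columns)
    x = df.to_numpy(dtype=float)
    n = x.shape[0]
    parents: dict[int, list[int]] = {i: [] for i in range(len(nodes))}
    for u, v in arcs:
        parents[nodes.index(v)].append(nodes.index(u))
    return float(sum(_node_score(x, i, tuple(sorted(ps)), n)
                     for i, ps in parents.items()))


def _creates_cycle(parents, u, v) -> bool:
    # would adding u -> v close a directed path v -> ... -> u?
    stack, seen = [u], set()
    while stack:
        node = stack.pop()
        if node == v:
            return True
        for q in parents[node]:
            if q not in seen:
                seen.add(q)
                stack.append(q)
    return False


def _greedy_climb(x, n, p, rng, parents=None):
    parents = parents if parents is not None else {i: set() for i in range(p)}
    scores = {i: _node_score(x, i, tuple(sorted(parents[i])), n) for i in range(p)}
    cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def node_score(child, ps):
        key = (child, tuple(sorted(ps)))
        if key not in cache:
            cache[key] = _node_score(x, child, key[1], n)
        return cache[key]

    while True:
        moves = []
        for u in range(p):
            for v in range(p):
                if u == v:
                    continue
                if u in parents[v]:
                    # delete u -> v
                    delta = node_score(v, parents[v] - {u}) - scores[v]
                    moves.append((delta, "del", u, v))
                    # reverse to v -> u
                    if not _creates_cycle({k: (s - {u} if k == v else s)
                                           for k, s in parents.items()}, v, u):
                        delta_r = (node_score(v, parents[v] - {u}) - scores[v]
                                   + node_score(u, parents[u] | {v}) - scores[u])
                        moves.append((delta_r, "rev", u, v))
                elif v not in parents[u] and not _creates_cycle(parents, u, v):
                    delta = node_score(v, parents[v] | {u}) - scores[v]
                    moves.append((delta, "add", u, v))
        if not moves:
            break
        best = max(m[0] for m in moves)
        if best <= 1e-9:
            break
        top = [m for m in moves if m[0] >= best - 1e-9]
        _, kind, u, v = top[int(rng.integers(len(top)))]
        if kind == "add":
            parents[v].add(u)
        elif kind == "del":
            parents[v].discard(u)
        else:  # reverse
            parents[v].discard(u)
            parents[u].add(v)
            scores[u] = node_score(u, parents[u])
        scores[v] = node_score(v, parents[v])
    total = sum(scores.values())
    return parents, total


def hill_climb_bn(data, restarts: int = 0, seed: int = 0) -> DirectedGraph:
    """Greedy hill climbing over DAGs maximising the Gaussian BIC.

    Starts from the empty graph; optional random restarts keep the best
    structure found.  Equally scoring moves are chosen uniformly at random,
    so Markov-equivalent orientations are sampled evenly.
    """
    df = _as_frame(data).dropna()
    nodes = list(df.columns)
    x = df.to_numpy(dtype=float)
    n, p = x.shape
    rng = np.random.default_rng(seed)
    best_parents, best_score = _greedy_climb(x, n, p, rng)
    for _ in range(restarts):
        init: dict[int, set[int]] = {i: set() for i in range(p)}
        order = rng.permutation(p)
        for ai in range(p):
            for bi in range(ai + 1, p):
                if rng.random() < 0.2:
                    init[order[bi]].add(order[ai])
        parents, score = _greedy_climb(x, n, p, rng, init)
        if score > best_score:
            best_parents, best_score = parents, score
    arcs = [(nodes[u], nodes[v]) for v in range(p)
            for u in sorted(best_parents[v])]
    return DirectedGraph(nodes, arcs, float(best_score))


def bootstrap_arcs(data, n_boot: int = 1000, direction_threshold: float = 0.51,
                   seed: int = 0, restarts: int = 0) -> DirectedGraph:
    """Bootstrap arc strengths and direction probabilities.

    Each resample (with replacement, same n) is refit by hill climbing.
    Pair strength is the fraction of refits containing the arc in either
    direction; the consensus keeps pairs with strength >= 0.5 and orients a
    pair only when its dominant direction reaches ``direction_threshold``
    (otherwise the edge is reported undirected).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0.5 < direction_threshold <= 1.0:
        raise ValueError("direction_threshold must lie in (0.5, 1]")
    if n_boot * (1.0 - direction_threshold) < 1 and n_boot < 1.0 / (2 * direction_threshold - 1.0):
        warnings.warn("n_boot is small relative to the direction threshold; "
                      "orientations may be unstable")
    df = _as_frame(data).dropna()
    nodes = list(df.columns)
    n = len(df)
    rng = np.random.default_rng(seed)
    pair_counts: dict[frozenset, int] = {}
    dir_counts: dict[tuple[str, str], int] = {}
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        fit = hill_climb_bn(df.iloc[idx], restarts=restarts,
                            seed=int(rng.integers(2**31)))
        for u, v in fit.arcs:
            pair_counts[frozenset((u, v))] = pair_counts.get(frozenset((u, v)), 0) + 1
            dir_counts[(u, v)] = dir_counts.get((u, v), 0) + 1

    strengths = {pair: cnt / n_boot for pair, cnt in pair_counts.items()}
    direction_probs = {}
    for (u, v), cnt in dir_counts.items():
        direction_probs[(u, v)] = cnt / pair_counts[frozenset((u, v))]

    arcs: list[tuple[str, str]] = []
    undirected: list[tuple[str, str]] = []
    for pair, s in sorted(strengths.items(), key=lambda kv: (-kv[1], sorted(kv[0]))):
        if s < 0.5:
            continue
        u, v = sorted(pair)
        p_uv = direction_probs.get((u, v), 0.0)
        p_vu = direction_probs.get((v, u), 0.0)
        if p_uv >= direction_threshold:
            arcs.append((u, v))
        elif p_vu >= direction_threshold:
            arcs.append((v, u))
        else:
            undirected.append((u, v))

    # consensus must stay acyclic: drop the weakest-direction arc of any cycle
    g = nx.DiGraph(arcs)
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        weakest = min(cycle, key=lambda e: direction_probs.get((e[0], e[1]), 0.0))
        g.remove_edge(*weakest)
        arcs = [a for a in arcs if a != (weakest[0], weakest[1])]
        undirected.append(tuple(sorted(weakest[:2])))

    score = bn_score(df, arcs) if arcs else bn_score(df, [])
    return DirectedGraph(nodes, arcs, float(score), strengths,
                         direction_probs, undirected)


def noa(data, baseline_vars, outcome_var: str, gamma: float = 0.5,
        method: str = "spearman"):
    """Joint network of baseline predictors and one follow-up outcome.

    Runs the graphical lasso on ``baseline_vars + [outcome_var]`` and
    returns the graph, its centrality table, and the outcome node's direct
    neighbours with edge weights.
    """
    baseline_vars = list(baseline_vars)
    if outcome_var in baseline_vars:
        raise ValueError("outcome variable must not appear among the baselines")
    df = _as_frame(data)
    missing = [v for v in baseline_vars + [outcome_var] if v not in df.columns]
    if missing:
        raise ValueError(f"variables not in data: {missing}")
    sub = df[baseline_vars + [outcome_var]]
    graph = glasso_network(sub, gamma=gamma, method=method)
    cent = centrality(graph)
    k = graph.nodes.index(outcome_var)
    neighbours = {graph.nodes[j]: float(graph.weights[k, j])
                  for j in range(len(graph.nodes))
                  if j != k and abs(graph.weights[k, j]) > 1e-8}
    return graph, cent, neighbours
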