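"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own linear algebra:
Betti numbers come from dense numpy mod-2 Gaussian elimination over
brute-force clique enumeration, and partial correlations from pairwise
least-squares residualization, so agreement with the package is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from wrcf.graphio import WeightedNetwork


# -- random fixtures -------------------------------------------------------


def random_weighted_network(rng: np.random.Generator, n_nodes: int,
                            p_edge: float = 0.5,
                            allow_ties: bool = False) -> WeightedNetwork:
    """Erdos-Renyi weighted network with at least one edge."""
    while True:
        net = WeightedNetwork.from_nodes(f"n{i}" for i in range(n_nodes))
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() < p_edge:
                    w = rng.random()
                    if allow_ties and rng.random() < 0.3:
                        w = round(w, 1)
                    net.add_edge(f"n{i}", f"n{j}", float(w), create_nodes=False)
        if net.n_edges:
            return net


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def square_with_diagonal():
    """The worked toy case: 4-cycle with boundary ranks 1-4 and a weak
    diagonal at rank 5 that closes the hole."""
    net = WeightedNetwork()
    for u, v, w in [("a", "b", 0.9), ("b", "c", 0.8), ("c", "d", 0.7),
                    ("a", "d", 0.6), ("a", "c", 0.1)]:
        net.add_edge(u, v, w)
    return net


# -- rank-based Betti oracle ----------------------------------------------


def _mod2_rank(m: np.ndarray) -> int:
    m = (np.asarray(m, dtype=np.int64) % 2).copy()
    rank = 0
    rows, cols = m.shape
    r = 0
    for c in range(cols):
        piv = None
        for i in range(r, rows):
            if m[i, c]:
                piv = i
                break
        if piv is None:
            continue
        m[[r, piv]] = m[[piv, r]]
        for i in range(rows):
            if i != r and m[i, c]:
                m[i] = (m[i] + m[r]) % 2
        r += 1
        rank += 1
    return rank


def oracle_betti(edges: set[tuple[int, int]], n_nodes: int,
                 max_dim: int = 1) -> list[int]:
    """Betti numbers of the clique complex of a binary graph, by explicit
    boundary matrices and mod-2 elimination. Enumerates simplices up to
    dimension max_dim + 1 by scanning all vertex subsets."""
    adj = {(min(e), max(e)) for e in edges}

    def is_clique(vs):
        return all((a, b) in adj for a, b in itertools.combinations(vs, 2))

    simplices = {0: [(v,) for v in range(n_nodes)]}
    for d in range(1, max_dim + 2):
        simplices[d] = [vs for vs in itertools.combinations(range(n_nodes), d + 1)
                        if is_clique(vs)]

    def boundary_matrix(d):
        rows = {s: i for i, s in enumerate(simplices[d - 1])}
        m = np.zeros((len(simplices[d - 1]), len(simplices[d])), dtype=np.int64)
        for j, s in enumerate(simplices[d]):
            for k in range(len(s)):
                m[rows[s[:k] + s[k + 1:]], j] = 1
        return m

    betti = []
    for k in range(max_dim + 1):
        n_k = len(simplices[k])
        rk = _mod2_rank(boundary_matrix(k)) if k > 0 and simplices[k] else 0
        rk1 = _mod2_rank(boundary_matrix(k + 1)) if simplices[k + 1] else 0
        betti.append(n_k - rk - rk1)
    return betti


def oracle_betti_curve(net: WeightedNetwork, max_dim: int = 1) -> list[list[int]]:
    """b_0..b_max_dim of the clique complex at every filtration step
    (index s = step, s = 0 is the vertex-only complex), via the
    brute-force oracle. The count of bars alive at step s in any valid
    barcode must equal these numbers."""
    from wrcf.filtration import rank_filtration

    filt = rank_filtration(net, max_clique_size=max_dim + 2)
    out = []
    for s in range(0, filt.n_steps + 1):
        edges = {e for e, r in filt.edge_rank.items() if r <= s}
        out.append(oracle_betti(edges, net.n_nodes, max_dim))
    return out


# -- residual-regression partial-correlation oracle ------------------------


def oracle_partial_correlation(X: np.ndarray, i: int, j: int) -> float:
    """Partial correlation of columns i, j of X given all other columns,
    by least-squares residualization."""
    n, p = X.shape
    others = [k for k in range(p) if k not in (i, j)]
    Z = np.column_stack([np.ones(n), X[:, others]])
    ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
    rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
    return float(np.corrcoef(ri, rj)[0, 1])
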