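"""Brute-force reachability oracles, independent of the graph library.

Component sizes are derived from all-pairs reachability computed by
repeated boolean squaring of the adjacency matrix — no traversal
algorithm shared with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def _closure(adj: np.ndarray) -> np.ndarray:
    """Reflexive-transitive closure by repeated boolean squaring."""
    n = adj.shape[0]
    reach = adj | np.eye(n, dtype=bool)
    while True:
        nxt = reach | (reach @ reach)
        if np.array_equal(nxt, reach):
            return reach
        reach = nxt


def _adjacency(nodes: list, edges: list[tuple]) -> np.ndarray:
    idx = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for a, b in edges:
        adj[idx[a], idx[b]] = True
    return adj


def brute_lcc(nodes: list, edges: list[tuple]) -> int:
    """Largest component size ignoring direction, via undirected closure."""
    adj = _adjacency(nodes, edges)
    reach = _closure(adj | adj.T)
    return int(max(reach[i].sum() for i in range(len(nodes))))


def brute_lsc(nodes: list, edges: list[tuple]) -> int:
    """Largest mutually-reachable node set, via R AND R-transpose."""
    reach = _closure(_adjacency(nodes, edges))
    mutual = reach & reach.T
    return int(max(mutual[i].sum() for i in range(len(nodes))))


def random_multigraph(rng: np.random.Generator) -> tuple[list, list[tuple]]:
    """Random directed multigraph on <= 12 nodes (self-loops, parallels)."""
    n = int(rng.integers(1, 13))
    nodes = list(range(n))
    n_edges = int(rng.integers(0, 3 * n + 1))
    edges = [
        (int(rng.integers(n)), int(rng.integers(n))) for _ in range(n_edges)
    ]
    return nodes, edges


def normal_equations_ols(X: np.ndarray, y: np.ndarray):
    """Textbook OLS: beta, SE, R^2 and overall F from the normal equations."""
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    rss = resid @ resid
    sigma2 = rss / (n - k)
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1 - rss / tss
    f = (tss - rss) / (k - 1) / sigma2
    return beta, se, r2, f
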