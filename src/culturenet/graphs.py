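"""Graph-theoretical characterization of structural networks.

Global efficiency, Newman modularity Q, average clustering, Louvain
community detection and matched Erdos-Renyi null models.  Following the
usual undirected-2m convention of the modularity definition, the directed
adjacency is symmetrized (an undirected edge exists if either direction
does) before computing these scalar measures; in-degree summaries use the
directed matrix (row = postsynaptic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "GraphMetrics",
    "symmetrize",
    "global_efficiency",
    "modularity",
    "detect_communities",
    "average_clustering",
    "er_null",
    "network_metrics",
    "connection_summaries",
]


@dataclass
class GraphMetrics:
    global_efficiency: float
    modularity_Q: float
    avg_clustering: float
    communities: np.ndarray
    null_stats: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "global_efficiency": self.global_efficiency,
            "modularity_Q": self.modularity_Q,
            "avg_clustering": self.avg_clustering,
            "n_communities": int(len(np.unique(self.communities))),
            "null_stats": self.null_stats,
        }


def _as_sparse(adjacency) -> sp.csr_matrix:
    a = adjacency.S if hasattr(adjacency, "S") else adjacency
    a = sp.csr_matrix(a)
    a = a.astype(np.int8)
    a.setdiag(0)
    a.eliminate_zeros()
    a.data[:] = 1
    return a


def symmetrize(adjacency) -> sp.csr_matrix:
    """Undirected binary adjacency: edge if either direction exists."""
    a = _as_sparse(adjacency)
    s = a.maximum(a.T)
    return s.tocsr()


def global_efficiency(adjacency) -> float:
    """Mean over ordered pairs of 1/d(i, j) on the symmetrized graph.

    ``d`` is the unweighted shortest-path length; disconnected pairs
    contribute 0.  Equals 1 for a complete graph.
    """
    s = symmetrize(adjacency)
    n = s.shape[0]
    if n < 2:
        raise ValueError("graph must have at least two nodes")
    d = shortest_path(s, method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def modularity(adjacency, labels) -> float:
    """Newman modularity Q of a node partition on the symmetrized graph.

    Q = (1/2m) sum_ij (a_ij - k_i k_j / 2m) delta(c_i, c_j).
    """
    s = symmetrize(adjacency)
    labels = np.asarray(labels)
    if len(labels) != s.shape[0]:
        raise ValueError("labels must cover all nodes")
    k = np.asarray(s.sum(axis=1), dtype=float).ravel()
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    coo = s.tocoo()
    same = labels[coo.row] == labels[coo.col]
    intra = coo.data[same].sum()  # counts each intra edge twice
    k_c = np.array([k[labels == c].sum() for c in np.unique(labels)])
    return float(intra / two_m - np.sum((k_c / two_m) ** 2))


def detect_communities(adjacency, rng=None, n_restarts: int = 10):
    """Louvain partition of the symmetrized graph; best Q of ``n_restarts``.

    Returns ``(labels, Q)``; seeded for reproducibility.
    """
    s = symmetrize(adjacency)
    g = nx.from_scipy_sparse_array(s)
    rng = np.random.default_rng(rng)
    best_labels, best_q = None, -np.inf
    for _ in range(max(1, n_restarts)):
        seed = int(rng.integers(0, 2**31 - 1))
        comms = nx.community.louvain_communities(g, seed=seed)
        labels = np.empty(s.shape[0], dtype=np.int64)
        for c, members in enumerate(comms):
            labels[list(members)] = c
        q = modularity(s, labels)
        if q > best_q:
            best_labels, best_q = labels, q
    return best_labels, float(best_q)


def average_clustering(adjacency) -> float:
    """Mean local clustering coefficient (degree < 2 nodes contribute 0)."""
    s = symmetrize(adjacency)
    g = nx.from_scipy_sparse_array(s)
    return float(nx.average_clustering(g, count_zeros=True))


def er_null(adjacency, n_draws: int = 10, rng=None) -> dict:
    """Directed Erdos-Renyi ensemble matched to the mean in-degree.

    Each draw uses edge probability ``<k_in>/(N-1)``; efficiency, Louvain
    modularity and clustering are computed per draw and summarized as
    mean and standard deviation.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    a = _as_sparse(adjacency)
    n = a.shape[0]
    p = a.nnz / (n * (n - 1))
    rng = np.random.default_rng(rng)
    effs, qs, cls = [], [], []
    for _ in range(n_draws):
        mask = rng.random((n, n)) < p
        np.fill_diagonal(mask, False)
        null = sp.csr_matrix(mask.astype(np.int8))
        effs.append(global_efficiency(null))
        _, q = detect_communities(null, rng=rng, n_restarts=1)
        qs.append(q)
        cls.append(average_clustering(null))
    return {
        "edge_probability": p,
        "global_efficiency": (float(np.mean(effs)), float(np.std(effs))),
        "modularity_Q": (float(np.mean(qs)), float(np.std(qs))),
        "avg_clustering": (float(np.mean(cls)), float(np.std(cls))),
    }


def network_metrics(adjacency, rng=None, n_null: int = 0) -> GraphMetrics:
    """Efficiency, Louvain Q and clustering, optionally with an ER null."""
    labels, q = detect_communities(adjacency, rng=rng)
    null = er_null(adjacency, n_null, rng=rng) if n_null else {}
    return GraphMetrics(
        global_efficiency=global_efficiency(adjacency),
        modularity_Q=q,
        avg_clustering=average_clustering(adjacency),
        communities=labels,
        null_stats=null,
    )


def connection_summaries(network) -> dict:
    """Per-edge lengths and angles plus the in-degree sequence.

    Edge angle is ``atan2`` of (postsynaptic - presynaptic) soma position;
    lengths are Euclidean soma-to-soma distances in mm.
    """
    s = _as_sparse(network.S).tocoo()
    pos = network.positions
    post, pre = s.row, s.col  # S[post, pre] = 1 encodes pre -> post
    delta = pos[post] - pos[pre]
    return {
        "lengths": np.hypot(delta[:, 0], delta[:, 1]),
        "angles": np.arctan2(delta[:, 1], delta[:, 0]),
        "in_degrees": np.asarray(network.S.sum(axis=1)).ravel(),
    }
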