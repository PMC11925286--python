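"""Contact networks: Watts-Strogatz generation, graph queries, betweenness.

The simulator runs both opinion diffusion and disease spread on a single
undirected contact network G(V, E).  Nodes are 0-based contiguous integers;
the network is stored as an edge array plus a cached sparse adjacency matrix
so per-step diffusion updates reduce to sparse matrix-vector products.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import igraph as ig
import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ContactNetwork",
    "generate_watts_strogatz",
    "betweenness_scores",
    "neighborhood_counts",
    "components_of_subset",
]


@dataclass
class ContactNetwork:
    """Undirected simple graph on nodes ``0..N-1``.

    Parameters
    ----------
    n_nodes : int
        Population size N.
    edges : ndarray of shape (M, 2)
        Unordered node pairs, one row per edge.  No self-loops, no
        duplicates (in either orientation).
    mean_degree_k, rewiring_p, seed
        Provenance metadata for generated small-world networks; ``None``
        for imported graphs.
    """

    n_nodes: int
    edges: np.ndarray
    mean_degree_k: int | None = None
    rewiring_p: float | None = None
    seed: int | None = None
    _adjacency: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= self.n_nodes:
                raise ValueError("edge endpoint outside 0..N-1")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-loops are not allowed")
            canon = np.sort(self.edges, axis=1)
            if len(np.unique(canon, axis=0)) != len(canon):
                raise ValueError("duplicate edges are not allowed")

    # -- cached views -------------------------------------------------

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric CSR adjacency matrix with int32 ones."""
        if self._adjacency is None:
            m = len(self.edges)
            if m == 0:
                self._adjacency = sp.csr_matrix(
                    (self.n_nodes, self.n_nodes), dtype=np.int32
                )
            else:
                i = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
                j = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
                data = np.ones(2 * m, dtype=np.int32)
                self._adjacency = sp.csr_matrix(
                    (data, (i, j)), shape=(self.n_nodes, self.n_nodes)
                )
        return self._adjacency

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def neighbors(self, i: int) -> np.ndarray:
        """Neighbor ids of node ``i`` (sorted)."""
        if not 0 <= i < self.n_nodes:
            raise KeyError(f"node {i} not in network of size {self.n_nodes}")
        a = self.adjacency
        return a.indices[a.indptr[i] : a.indptr[i + 1]].astype(np.int64)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g

    def to_igraph(self) -> ig.Graph:
        return ig.Graph(n=self.n_nodes, edges=self.edges.tolist(), directed=False)

    @classmethod
    def from_networkx(cls, g: nx.Graph, **meta) -> "ContactNetwork":
        mapping = {u: idx for idx, u in enumerate(g.nodes())}
        edges = np.array(
            [(mapping[u], mapping[v]) for u, v in g.edges()], dtype=np.int64
        ).reshape(-1, 2)
        return cls(n_nodes=g.number_of_nodes(), edges=edges, **meta)


def generate_watts_strogatz(
    n: int, k: int, p: float, rng: np.random.Generator | int | None = None
) -> ContactNetwork:
    """Generate a Watts-Strogatz small-world network.

    Starts from a ring lattice where node ``i`` is adjacent to its ``k/2``
    nearest neighbors on each side, then rewires each edge with probability
    ``p`` (avoiding self-loops and duplicates), preserving the edge count
    ``N*k/2``.

    Raises
    ------
    ValueError
        If ``k`` is odd, ``k >= n``, ``k < 2`` or ``p`` outside [0, 1].
    """
    if k % 2 != 0:
        raise ValueError(f"mean degree k must be even, got {k}")
    if not (2 <= k < n):
        raise ValueError(f"require 2 <= k < N, got k={k}, N={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"rewiring probability p must be in [0, 1], got {p}")
    rng = np.random.default_rng(rng)
    # networkx expects an integer-seedable RandomState-compatible source;
    # feed it a child generator so the caller's stream ordering is stable.
    nx_seed = int(rng.integers(0, 2**32 - 1))
    g = nx.watts_strogatz_graph(n, k, p, seed=nx_seed)
    net = ContactNetwork.from_networkx(
        g, mean_degree_k=k, rewiring_p=p, seed=nx_seed
    )
    return net


def betweenness_scores(net: ContactNetwork) -> np.ndarray:
    """Unnormalized shortest-path betweenness for every node.

    Pairs connected by multiple shortest paths contribute fractionally
    (Brandes' algorithm); each unordered pair is counted once.  Returns an
    array indexed by node id.
    """
    if net.n_nodes == 0:
        return np.zeros(0, dtype=float)
    scores = net.to_igraph().betweenness(directed=False)
    return np.asarray(scores, dtype=float)


def neighborhood_counts(
    net: ContactNetwork, states: np.ndarray, i: int
) -> tuple[int, int, int]:
    """Counts ``(n_minus, n_zero, n_plus)`` of node ``i``'s neighbors by
    opinion state.  ``states`` uses -1 (negative), 0 (neutral), +1 (positive).
    """
    nbrs = net.neighbors(i)
    s = states[nbrs]
    return int(np.sum(s == -1)), int(np.sum(s == 0)), int(np.sum(s == 1))


def components_of_subset(
    net: ContactNetwork, subset: Iterable[int] | np.ndarray
) -> list[set[int]]:
    """Connected components of the subgraph induced by ``subset``.

    Returns a list of disjoint node sets whose union equals ``subset``.
    """
    nodes = np.asarray(sorted(set(int(v) for v in subset)), dtype=np.int64)
    if nodes.size == 0:
        return []
    if np.any(nodes < 0) or np.any(nodes >= net.n_nodes):
        raise KeyError("subset contains node ids outside the network")
    sub = net.adjacency[nodes][:, nodes]
    n_comp, labels = connected_components(sub, directed=False)
    comps: list[set[int]] = [set() for _ in range(n_comp)]
    for node, lab in zip(nodes, labels):
        comps[lab].add(int(node))
    return comps
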