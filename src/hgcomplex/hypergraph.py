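"""Attributed hypergraph construction from a PPI network.

The PPI graph is lifted to a hypergraph whose hyperedges are the maximal
cliques (fully connected subgraphs): proteins that are all pairwise
interacting plausibly act as one higher-order unit. The incidence matrix
H (|V| x |E|, H[i,k] = 1 iff node i in hyperedge k), hyperedge weights W
(all ones by default) and the node feature matrix X together form the
attributed hypergraph consumed by the encoder.

The propagation operator is the symmetrically normalized hypergraph
smoothing kernel

    A = D_v^{-1/2} H W D_e^{-1} H^T D_v^{-1/2}

with D_v the (weighted) vertex hyperdegrees and D_e the hyperedge
cardinalities. With W = I it is a symmetrized random walk: spectral
radius 1, and D_v^{1/2} 1 is the eigenvector of eigenvalue 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import InteractionNetwork

__all__ = [
    "AttributedHypergraph",
    "enumerate_clique_hyperedges",
    "build_hypergraph",
    "propagation_operator",
    "write_hyperedges",
]


@dataclass
class AttributedHypergraph:
    nodes: list[str]
    hyperedges: list[frozenset[int]]  # node-index sets
    H: np.ndarray                     # |V| x |E| binary incidence
    W: np.ndarray                     # |E| positive hyperedge weights
    X: np.ndarray | None = None       # |V| x d node features

    def __post_init__(self) -> None:
        n, m = self.H.shape
        if n != len(self.nodes) or m != len(self.hyperedges):
            raise ValueError("incidence matrix shape mismatch")
        if np.any(self.W <= 0):
            raise ValueError("hyperedge weights must be strictly positive")
        if self.X is not None and self.X.shape[0] != n:
            raise ValueError("feature matrix row count mismatch")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_hyperedges(self) -> int:
        return len(self.hyperedges)

    @property
    def vertex_degrees(self) -> np.ndarray:
        """Weighted vertex hyperdegrees: D_v[i] = sum_k W[k] H[i,k]."""
        return self.H @ self.W

    @property
    def hyperedge_degrees(self) -> np.ndarray:
        """Hyperedge cardinalities: D_e[k] = sum_i H[i,k]."""
        return self.H.sum(axis=0)

    def memberships(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (node_index, hyperedge_index) membership pairs,
        grouped by hyperedge in hyperedge order."""
        node_idx = []
        edge_idx = []
        for k, members in enumerate(self.hyperedges):
            for i in sorted(members):
                node_idx.append(i)
                edge_idx.append(k)
        return np.asarray(node_idx, dtype=int), np.asarray(edge_idx, dtype=int)


def enumerate_clique_hyperedges(
    network: InteractionNetwork, min_size: int = 3
) -> list[frozenset[str]]:
    """All maximal cliques of the network with size >= min_size.

    Output order is deterministic: sorted by the sorted member tuple.
    """
    if network.n_nodes == 0:
        raise ValueError("empty network")
    g = network.to_networkx()
    cliques = [frozenset(c) for c in nx.find_cliques(g) if len(c) >= min_size]
    return sorted(cliques, key=lambda c: tuple(sorted(c)))


def build_hypergraph(
    network: InteractionNetwork,
    X: np.ndarray | None = None,
    min_size: int = 3,
) -> AttributedHypergraph:
    """Lift a PPI network to an attributed hypergraph.

    Hyperedges are maximal cliques of size >= min_size. Any node covered
    by no clique (possible when min_size > 2) receives a singleton
    hyperedge so every vertex degree is positive. W is initialized to 1.
    """
    if network.n_nodes == 0:
        raise ValueError("empty network")
    if X is not None and X.shape[0] != network.n_nodes:
        raise ValueError("feature matrix rows must align with network nodes")
    index_of = {pid: i for i, pid in enumerate(network.nodes)}
    cliques = enumerate_clique_hyperedges(network, min_size=min_size)
    hyperedges = [frozenset(index_of[p] for p in c) for c in cliques]
    covered = set().union(*hyperedges) if hyperedges else set()
    for i in range(network.n_nodes):
        if i not in covered:
            hyperedges.append(frozenset([i]))
    n, m = network.n_nodes, len(hyperedges)
    H = np.zeros((n, m), dtype=float)
    for k, members in enumerate(hyperedges):
        for i in members:
            H[i, k] = 1.0
    return AttributedHypergraph(
        nodes=list(network.nodes), hyperedges=hyperedges, H=H,
        W=np.ones(m, dtype=float), X=X,
    )


def propagation_operator(hg: AttributedHypergraph) -> np.ndarray:
    """The normalized smoothing kernel A = Dv^{-1/2} H W De^{-1} H^T Dv^{-1/2}."""
    dv = hg.vertex_degrees
    de = hg.hyperedge_degrees
    if np.any(dv <= 0):
        bad = [hg.nodes[i] for i in np.flatnonzero(dv <= 0)]
        raise ValueError(
            f"zero vertex hyperdegree for {bad}; add coverage hyperedges "
            "(build_hypergraph does this automatically)"
        )
    if np.any(de <= 0):
        raise ValueError("empty hyperedge")
    dv_isqrt = 1.0 / np.sqrt(dv)
    HW = hg.H * hg.W[None, :]
    inner = (HW / de[None, :]) @ hg.H.T
    A = dv_isqrt[:, None] * inner * dv_isqrt[None, :]
    return (A + A.T) / 2.0  # kill round-off asymmetry


def write_hyperedges(hg: AttributedHypergraph, path) -> None:
    """Export the hyperedge list, one hyperedge per line, tab-separated ids."""
    with open(path, "w") as fh:
        for members in hg.hyperedges:
            fh.write("\t".join(sorted(hg.nodes[i] for i in members)) + "\n")
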