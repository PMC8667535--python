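"""Temporal proximity graph G_t built from individual positions.

An undirected edge (u, v) exists at epoch t iff the Euclidean distance
between the two individuals is at most the contact threshold ``d`` (the
boundary case counts: "within" is a closed threshold).  Construction uses
a k-d tree; tests hold it oracle-equivalent to the naive pairwise check.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .population import Population

__all__ = [
    "ContactNetwork",
    "build_contact_network",
    "neighbor_list",
    "max_degree",
    "write_edge_list",
]


@dataclass
class ContactNetwork:
    """Undirected proximity graph over individual ids at one epoch."""

    graph: nx.Graph
    epoch: int = 0

    @classmethod
    def from_positions(cls, ids, positions: np.ndarray, d: float, epoch: int = 0) -> "ContactNetwork":
        """Build the graph from an (n, 2) position array (edges iff distance <= d)."""
        if d <= 0:
            raise ValueError("contact threshold d must be positive")
        ids = list(ids)
        g = nx.Graph()
        g.add_nodes_from(ids)
        if len(ids) > 1:
            tree = cKDTree(np.asarray(positions, dtype=float))
            for i, j in tree.query_pairs(r=d):  # query_pairs is inclusive of r
                g.add_edge(ids[i], ids[j])
        return cls(graph=g, epoch=epoch)

    @classmethod
    def from_edges(cls, edges, nodes=None, epoch: int = 0) -> "ContactNetwork":
        """Build directly from an explicit edge list (for analysis/tests)."""
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return cls(graph=g, epoch=epoch)

    def nodes(self):
        return list(self.graph.nodes)

    def edges(self):
        return list(self.graph.edges)

    def has_edge(self, u, v) -> bool:
        return self.graph.has_edge(u, v)

    def degree(self, u) -> int:
        return self.graph.degree[u]

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()


def build_contact_network(population: Population, d: float) -> ContactNetwork:
    """Proximity graph over a population at its current positions."""
    ids = [ind.id for ind in population]
    return ContactNetwork.from_positions(
        ids, population.positions_array(), d, epoch=population.epoch
    )


def neighbor_list(network: ContactNetwork, u) -> set:
    """n_t(u): the ids within contact distance of u at this epoch."""
    if u not in network.graph:
        raise KeyError(f"unknown node id: {u!r}")
    return set(network.graph.neighbors(u))


def max_degree(network: ContactNetwork) -> int:
    """M_t: the maximum number of neighbors of any node (0 if edgeless)."""
    degrees = [deg for _, deg in network.graph.degree]
    return max(degrees, default=0)


def write_edge_list(network: ContactNetwork, path) -> None:
    """Plain two-column text export: 'u v', one edge per line."""
    with open(path, "w") as fh:
        for u, v in network.graph.edges:
            fh.write(f"{u} {v}\n")
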