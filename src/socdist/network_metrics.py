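"""Network-science instrumentation: clustering, homophily, contagion potential.

Contagion potential (CP) quantifies how likely a node is to act as a
spreader.  The instantaneous value propagates from infected contacts:

    P_t(u) = 0                          at t = 0
           = 1                          while u is infected (t >= 1)
           = sum_{v in n_t(u)} P_{t-1}(v) / M_t   otherwise,

where M_t is the maximum degree in the epoch-t contact network, so the
value stays in [0, 1].  The overall potential Z_t(u) is the running mean
of the instantaneous values, pinned to 0 for recovered/dead nodes and 1
for infected ones.  Homophily is measured by the E-I index,
(external - internal) / (external + internal) edge counts over a group
assignment: -1 is complete homophily, +1 complete heterophily.
"""

from __future__ import annotations

import math

import networkx as nx

from .contact_network import ContactNetwork, max_degree
from .population import EpidemicState

__all__ = [
    "node_clustering",
    "average_clustering",
    "ei_index",
    "instantaneous_cp",
    "overall_cp",
    "discretize_cp",
    "write_cp_csv",
]


def node_clustering(network: ContactNetwork, u) -> float:
    """Clustering coefficient 2*t(u) / (deg(u)*(deg(u)-1)); 0 below degree 2."""
    if u not in network.graph:
        raise KeyError(f"unknown node id: {u!r}")
    return nx.clustering(network.graph, u)


def average_clustering(network: ContactNetwork) -> float:
    """Mean node clustering over all nodes (isolated nodes count as 0)."""
    if network.graph.number_of_nodes() == 0:
        raise ValueError("clustering undefined for an empty graph")
    return nx.average_clustering(network.graph, count_zeros=True)


def ei_index(network: ContactNetwork, groups: dict) -> float:
    """E-I homophily index over a total group assignment.

    external = edges whose endpoints carry different group labels,
    internal = same-group edges; the index is their normalized difference.
    Raises on an edgeless graph, where the proportion is undefined.
    """
    edges = list(network.graph.edges)
    if not edges:
        raise ValueError("E-I index undefined for an edgeless graph")
    external = sum(1 for u, v in edges if groups[u] != groups[v])
    internal = len(edges) - external
    return (external - internal) / (external + internal)


def instantaneous_cp(
    prev_cp: dict,
    network: ContactNetwork,
    states: dict,
    t: int,
) -> dict:
    """One propagation step of the instantaneous contagion potential P_t.

    ``prev_cp`` maps each node to P_{t-1}.  An edgeless epoch (M_t = 0)
    gives every non-infected node 0: no contacts, no acquired potential.
    """
    if t == 0:
        return {u: 0.0 for u in network.graph.nodes}
    m_t = max_degree(network)
    cp: dict = {}
    for u in network.graph.nodes:
        if states[u] is EpidemicState.I:
            cp[u] = 1.0
        elif m_t == 0:
            cp[u] = 0.0
        else:
            cp[u] = sum(prev_cp[v] for v in network.graph.neighbors(u)) / m_t
    return cp


def overall_cp(cp_history: dict, states: dict, t: int) -> dict:
    """Overall contagion potential Z_t: running mean of P_1..P_t per node.

    Pinned to 0 for recovered/dead nodes and to 1 for infected nodes.
    ``cp_history`` maps each node to its sequence of instantaneous values.
    """
    z: dict = {}
    for u, history in cp_history.items():
        if len(history) != t:
            raise ValueError(f"node {u!r}: history length {len(history)} != t={t}")
        if states[u] in (EpidemicState.R, EpidemicState.D):
            z[u] = 0.0
        elif states[u] is EpidemicState.I:
            z[u] = 1.0
        else:
            if t == 0:
                raise ValueError("overall CP undefined from an empty history")
            z[u] = sum(history) / t
    return z


def _round_half_away(value: float, decimals: int) -> float:
    """Round half away from zero (0.05 -> 0.1 at one decimal)."""
    factor = 10.0 ** decimals
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


def discretize_cp(cp: dict, decimals: int = 1) -> dict:
    """Group nodes by their CP rounded half-away-from-zero to ``decimals``."""
    if decimals < 1:
        raise ValueError("decimals must be >= 1")
    return {u: _round_half_away(v, decimals) for u, v in cp.items()}


def write_cp_csv(path, p_t: dict, z_t: dict, groups: dict) -> None:
    """CP export CSV with columns id,P_t,Z_t,group."""
    import pandas as pd

    ids = sorted(p_t)
    pd.DataFrame(
        {
            "id": ids,
            "P_t": [p_t[u] for u in ids],
            "Z_t": [z_t[u] for u in ids],
            "group": [groups[u] for u in ids],
        }
    ).to_csv(path, index=False)
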