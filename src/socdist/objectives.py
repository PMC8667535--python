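"""Social-distancing objective scores and the movement-feasibility constraint.

Each relocation strategy minimizes one of three scores on the current
contact network (recovered and dead nodes are excluded everywhere — they
impose no relocation pressure):

* ``direct_contact`` — the number of edges joining an infected node to a
  susceptible or exposed one (susceptible and exposed are pooled because
  both are asymptomatic and indistinguishable in the field).
* ``clustering`` — the number of triangles containing at least one
  susceptible-or-exposed member and at least one infected member; dense
  triads around an infected node are contagion hot-spots.
* ``contagion_potential`` — the total |Z(u) - Z(v)| over edges among
  live (S/E/I) nodes: minimizing it groups nodes of similar contagion
  potential (homophily) and severs high-contrast contacts.  With a binary
  CP (1 on infected, 0 elsewhere) it reduces to the direct-contact count.

Feasibility: any proposed move must stay within the movement threshold
tau of the current location.
"""

from __future__ import annotations

from enum import Enum
from itertools import combinations

import numpy as np

from .contact_network import ContactNetwork
from .population import Coordinate, EpidemicState

__all__ = [
    "ObjectiveKind",
    "direct_contact_score",
    "triangle_score",
    "cp_score",
    "movement_feasible",
    "score",
    "ObjectiveEvaluator",
]


class ObjectiveKind(Enum):
    DIRECT_CONTACT = "direct_contact"
    CLUSTERING = "clustering"
    CONTAGION_POTENTIAL = "contagion_potential"


_SE = (EpidemicState.S, EpidemicState.E)
_LIVE = (EpidemicState.S, EpidemicState.E, EpidemicState.I)


def direct_contact_score(network: ContactNetwork, states: dict) -> int:
    """Count of edges between an S/E node and an I node."""
    total = 0
    for u, v in network.graph.edges:
        su, sv = states[u], states[v]
        if (su in _SE and sv is EpidemicState.I) or (sv in _SE and su is EpidemicState.I):
            total += 1
    return total


def triangle_score(network: ContactNetwork, states: dict) -> int:
    """Triangles with at least one S/E member and at least one I member.

    Each unordered triple counts once.  Triples are enumerated over the
    subgraph of live nodes via edge + common-neighbor iteration.
    """
    g = network.graph
    total = 0
    for u, v in g.edges:
        if states[u] not in _LIVE or states[v] not in _LIVE:
            continue
        # count each triangle once: only take the common neighbor w > u, v
        for w in g.adj[u].keys() & g.adj[v].keys():
            if w > u and w > v and states[w] in _LIVE:
                trio = (states[u], states[v], states[w])
                if any(s in _SE for s in trio) and any(s is EpidemicState.I for s in trio):
                    total += 1
    return total


def cp_score(network: ContactNetwork, states: dict, cp: dict) -> float:
    """Sum of |Z(u) - Z(v)| over edges with both endpoints in S/E/I."""
    total = 0.0
    for u, v in network.graph.edges:
        if states[u] in _LIVE and states[v] in _LIVE:
            total += abs(cp[u] - cp[v])
    return total


def movement_feasible(old: Coordinate, new: Coordinate, tau: float) -> bool:
    """True iff the displacement does not exceed the movement threshold."""
    return old.distance_to(new) <= tau


def score(
    kind: ObjectiveKind,
    network: ContactNetwork,
    states: dict,
    cp: dict | None = None,
):
    """Dispatch to the objective named by ``kind``."""
    if kind is ObjectiveKind.DIRECT_CONTACT:
        return direct_contact_score(network, states)
    if kind is ObjectiveKind.CLUSTERING:
        return triangle_score(network, states)
    if kind is ObjectiveKind.CONTAGION_POTENTIAL:
        if cp is None:
            raise ValueError("contagion_potential objective requires CP values")
        return cp_score(network, states, cp)
    raise ValueError(f"unknown objective kind: {kind!r}")


# --- incremental evaluation engine -----------------------------------------
#
# Moving one node only changes the edges (and triangles) incident to it, so
# a candidate location can be scored from the node's local contribution
# alone.  The evaluator keeps a dense boolean adjacency (populations here
# are at most a few thousand) and updates one row/column per accepted move.

# integer codes matching population.STATE_CODES order (S,E,I,R,D)
_C_S, _C_E, _C_I = 0, 1, 2


class ObjectiveEvaluator:
    """Full and single-node-delta scoring over array-based state.

    Parameters
    ----------
    positions : (n, 2) float array, row i = node i's location.
    states : (n,) int array of compartment codes (S=0,E=1,I=2,R=3,D=4).
    d : contact threshold in feet.
    kind : which objective to score.
    cp : (n,) float array of overall contagion potentials (required for
        the contagion-potential objective).
    """

    def __init__(self, positions, states, d, kind: ObjectiveKind, cp=None):
        self.pos = np.array(positions, dtype=float)
        self.states = np.asarray(states)
        self.d = float(d)
        self.kind = kind
        n = len(self.pos)
        if kind is ObjectiveKind.CONTAGION_POTENTIAL:
            if cp is None:
                raise ValueError("contagion_potential objective requires CP values")
            self.cp = np.asarray(cp, dtype=float)
        else:
            self.cp = None
        self.se = (self.states == _C_S) | (self.states == _C_E)
        self.inf = self.states == _C_I
        self.live = self.se | self.inf
        diff = self.pos[:, None, :] - self.pos[None, :, :]
        dist2 = np.einsum("ijk,ijk->ij", diff, diff)
        self.adj = dist2 <= self.d ** 2
        np.fill_diagonal(self.adj, False)

    # -- full score ----------------------------------------------------

    def full_score(self) -> float:
        return self._total_from_adj(self.adj)

    def _total_from_adj(self, adj) -> float:
        if self.kind is ObjectiveKind.DIRECT_CONTACT:
            return float(np.count_nonzero(adj[self.se][:, self.inf]))
        if self.kind is ObjectiveKind.CONTAGION_POTENTIAL:
            live_adj = adj & self.live[:, None] & self.live[None, :]
            iu, iv = np.nonzero(np.triu(live_adj, 1))
            return float(np.abs(self.cp[iu] - self.cp[iv]).sum())
        # clustering: triangles among live nodes minus the all-SE and
        # all-I ones (a live triangle violates the condition only when it
        # has no I member or no S/E member)
        return (
            self._triangles(adj, self.live)
            - self._triangles(adj, self.se)
            - self._triangles(adj, self.inf)
        )

    @staticmethod
    def _triangles(adj, mask) -> float:
        sub = adj[np.ix_(mask, mask)].astype(np.float64)
        return float(np.trace(sub @ sub @ sub) / 6.0)

    # -- single-node contribution ---------------------------------------

    def neighbor_row(self, u: int, position) -> np.ndarray:
        """Boolean contact row of node ``u`` if it stood at ``position``."""
        diff = self.pos - np.asarray(position, dtype=float)
        row = np.einsum("ij,ij->i", diff, diff) <= self.d ** 2
        row[u] = False
        return row

    def node_contribution(self, u: int, row: np.ndarray) -> float:
        """The part of the score contributed by edges/triangles through u."""
        if self.kind is ObjectiveKind.DIRECT_CONTACT:
            if self.se[u]:
                return float(np.count_nonzero(row & self.inf))
            if self.inf[u]:
                return float(np.count_nonzero(row & self.se))
            return 0.0
        if self.kind is ObjectiveKind.CONTAGION_POTENTIAL:
            if not self.live[u]:
                return 0.0
            nb = row & self.live
            return float(np.abs(self.cp[nb] - self.cp[u]).sum())
        # clustering: triangles through u = connected pairs of u's live
        # neighbors, filtered by the state condition given u's own state
        if not self.live[u]:
            return 0.0
        nb = np.nonzero(row & self.live)[0]
        if len(nb) < 2:
            return 0.0
        sub = self.adj[np.ix_(nb, nb)]
        pairs_all = np.count_nonzero(sub) / 2.0
        if self.se[u]:
            # need >=1 I among {v, w}; subtract pairs with no I member
            no_i = ~self.inf[nb]
            pairs_no_i = np.count_nonzero(sub[np.ix_(no_i, no_i)]) / 2.0
            return pairs_all - pairs_no_i
        # u infected: need >=1 S/E among {v, w}
        no_se = ~self.se[nb]
        pairs_no_se = np.count_nonzero(sub[np.ix_(no_se, no_se)]) / 2.0
        return pairs_all - pairs_no_se

    def move_delta(self, u: int, position) -> tuple[float, np.ndarray]:
        """Score change if node ``u`` relocates to ``position``."""
        old = self.node_contribution(u, self.adj[u])
        new_row = self.neighbor_row(u, position)
        new = self.node_contribution(u, new_row)
        return new - old, new_row

    def commit_move(self, u: int, position, row: np.ndarray) -> None:
        """Apply an accepted relocation of node ``u``."""
        self.pos[u] = position
        self.adj[u, :] = row
        self.adj[:, u] = row
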