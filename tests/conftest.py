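import numpy as np
import pytest

from socdist import (
    Coordinate,
    EpidemicState,
    Individual,
    Population,
    RegionSpec,
)


@pytest.fixture
def region():
    return RegionSpec(X=100.0, Y=100.0, d=6.0, tau=25.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_population(specs, epoch=0):
    """Population from [(x, y, state_letter), ...]; ids follow list order."""
    individuals = [
        Individual(
            id=i,
            position=Coordinate(float(x), float(y)),
            state=EpidemicState(s),
            overall_cp=1.0 if s == "I" else 0.0,
        )
        for i, (x, y, s) in enumerate(specs)
    ]
    return Population(individuals=individuals, epoch=epoch)


# --- independent brute-force oracles (kept free of the package's own
#     graph/score code paths) ----------------------------------------------


def brute_force_edges(positions, d):
    """Naive O(n^2) pairwise proximity check."""
    n = len(positions)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            dx = positions[i][0] - positions[j][0]
            dy = positions[i][1] - positions[j][1]
            if (dx * dx + dy * dy) ** 0.5 <= d:
                edges.add((i, j))
    return edges


def brute_force_clustering(adj, u):
    """Clustering of u by direct triangle enumeration over its neighbors."""
    nbrs = sorted(adj[u])
    deg = len(nbrs)
    if deg < 2:
        return 0.0
    triangles = 0
    for a in range(deg):
        for b in range(a + 1, deg):
            if nbrs[b] in adj[nbrs[a]]:
                triangles += 1
    return 2.0 * triangles / (deg * (deg - 1))


def brute_force_direct_contact(edges, states):
    total = 0
    for u, v in edges:
        pair = {states[u], states[v]}
        if "I" in pair and ({"S", "E"} & pair):
            total += 1
    return total


def brute_force_triangle_score(nodes, edge_set, states):
    """Enumerate every unordered triple and apply the state condition."""
    from itertools import combinations

    def connected(a, b):
        return (a, b) in edge_set or (b, a) in edge_set

    total = 0
    for u, v, w in combinations(sorted(nodes), 3):
        if not (connected(u, v) and connected(v, w) and connected(u, w)):
            continue
        trio = [states[u], states[v], states[w]]
        if any(s in ("R", "D") for s in trio):
            continue
        if any(s in ("S", "E") for s in trio) and any(s == "I" for s in trio):
            total += 1
    return total
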