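"""Individuals, the deployment region, and bounded random mobility.

The simulated world is a rectangular urban space of ``X`` x ``Y`` square
feet in which ``n`` mobile individuals are placed.  Two thresholds govern
everything downstream: the *contact threshold* ``d`` (two individuals
within ``d`` feet of each other form a social tie, i.e. a potential
transmission contact) and the *movement threshold* ``tau`` (the farthest
an individual may move between consecutive time epochs; it is a hard
feasibility bound for the relocation optimizers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Coordinate",
    "RegionSpec",
    "EpidemicState",
    "Individual",
    "Population",
    "generate_population",
    "random_move",
    "clip_to_region",
    "read_snapshot",
    "write_snapshot",
]


@dataclass(frozen=True)
class Coordinate:
    """A continuous 2-D location in feet, origin at the bottom-left corner."""

    x: float
    y: float

    def distance_to(self, other: "Coordinate") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class RegionSpec:
    """Deployment region with its contact and movement thresholds.

    Parameters
    ----------
    X, Y:
        Region dimensions in feet.
    d:
        Contact threshold in feet; two individuals at distance <= d share
        a social tie.  Default 6 ft.
    tau:
        Movement threshold in feet; the maximum displacement per epoch
        and the grid padding width.  Default 25 ft.
    """

    X: float
    Y: float
    d: float = 6.0
    tau: float = 25.0

    def __post_init__(self) -> None:
        if self.X <= 0 or self.Y <= 0:
            raise ValueError("region dimensions X, Y must be positive")
        if self.d <= 0:
            raise ValueError("contact threshold d must be positive")
        if self.tau <= 0:
            raise ValueError("movement threshold tau must be positive")

    def contains(self, position: Coordinate) -> bool:
        return 0.0 <= position.x <= self.X and 0.0 <= position.y <= self.Y


class EpidemicState(Enum):
    """SEIRD compartment of an individual (exactly one at all times)."""

    S = "S"
    E = "E"
    I = "I"
    R = "R"
    D = "D"


# integer codes used by the vectorized internals
STATE_CODES = {s: i for i, s in enumerate(EpidemicState)}
CODE_STATES = {i: s for s, i in STATE_CODES.items()}


@dataclass
class Individual:
    """One agent: identity, location, compartment and contagion potential.

    ``cp_history`` holds the instantaneous contagion-potential values
    P_1..P_t; ``overall_cp`` is the running summary Z_t(u) in [0, 1]
    (0 for recovered/dead, 1 while infected, otherwise the mean of the
    instantaneous values).
    """

    id: int
    position: Coordinate
    state: EpidemicState
    cp_history: list[float] = field(default_factory=list)
    overall_cp: float = 0.0


@dataclass
class Population:
    """All individuals at a given epoch; size is conserved (the dead stay)."""

    individuals: list[Individual]
    epoch: int = 0

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("individual ids must be unique")
        self.individuals.sort(key=lambda ind: ind.id)

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def positions_array(self) -> np.ndarray:
        """(n, 2) float array of positions, ordered by id."""
        return np.array([[i.position.x, i.position.y] for i in self.individuals])

    def states_array(self) -> np.ndarray:
        """(n,) int8 array of compartment codes, ordered by id."""
        return np.array([STATE_CODES[i.state] for i in self.individuals], dtype=np.int8)

    def cp_array(self) -> np.ndarray:
        """(n,) float array of overall contagion potentials Z_t."""
        return np.array([i.overall_cp for i in self.individuals])

    def state_counts(self) -> dict[EpidemicState, int]:
        counts = {s: 0 for s in EpidemicState}
        for ind in self.individuals:
            counts[ind.state] += 1
        return counts

    def set_positions(self, positions: np.ndarray) -> None:
        """Overwrite all positions from an (n, 2) array ordered by id."""
        if positions.shape != (len(self.individuals), 2):
            raise ValueError("positions array shape must be (n, 2)")
        for ind, (x, y) in zip(self.individuals, positions):
            ind.position = Coordinate(float(x), float(y))


def clip_to_region(position: Coordinate, region: RegionSpec) -> Coordinate:
    """Coordinatewise clamp into [0, X] x [0, Y]."""
    return Coordinate(
        min(max(position.x, 0.0), region.X),
        min(max(position.y, 0.0), region.Y),
    )


def random_move(
    position: Coordinate,
    tau: float,
    region: RegionSpec,
    rng: np.random.Generator,
) -> Coordinate:
    """Uniform draw from the disk of radius ``tau`` around ``position``.

    The result is clipped to the region.  Because the starting point lies
    inside the region, per-axis clamping can only shrink each displacement
    component, so the hard bound ``distance <= tau`` survives clipping.
    """
    r = tau * math.sqrt(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * math.pi)
    target = Coordinate(position.x + r * math.cos(theta), position.y + r * math.sin(theta))
    return clip_to_region(target, region)


def generate_population(
    n: int,
    region: RegionSpec,
    init_fractions: tuple[float, float] = (0.7, 0.3),
    seed: int = 0,
) -> Population:
    """Seeded synthetic population with uniform positions.

    ``init_fractions`` is (susceptible fraction, infected fraction); the
    susceptible count is ``n * f_S`` rounded half up and the remainder
    starts infected.  Ids run 0..n-1 and the epoch starts at 0.
    """
    if n < 1:
        raise ValueError("population size n must be >= 1")
    f_s, f_i = init_fractions
    if not (0.0 <= f_s <= 1.0 and 0.0 <= f_i <= 1.0):
        raise ValueError("initial fractions must lie in [0, 1]")
    if abs(f_s + f_i - 1.0) > 1e-9:
        raise ValueError("initial susceptible and infected fractions must sum to 1")

    rng = np.random.default_rng(seed)
    xs = rng.uniform(0.0, region.X, size=n)
    ys = rng.uniform(0.0, region.Y, size=n)
    n_s = int(math.floor(n * f_s + 0.5))  # round half up
    states = [EpidemicState.S] * n_s + [EpidemicState.I] * (n - n_s)

    individuals = [
        Individual(
            id=i,
            position=Coordinate(float(xs[i]), float(ys[i])),
            state=states[i],
            overall_cp=1.0 if states[i] is EpidemicState.I else 0.0,
        )
        for i in range(n)
    ]
    return Population(individuals=individuals, epoch=0)


def write_snapshot(population: Population, path) -> None:
    """Write a population snapshot CSV with columns id,x,y,state,cp."""
    df = pd.DataFrame(
        {
            "id": [i.id for i in population],
            "x": [i.position.x for i in population],
            "y": [i.position.y for i in population],
            "state": [i.state.value for i in population],
            "cp": [i.overall_cp for i in population],
        }
    )
    df.to_csv(path, index=False)


def read_snapshot(path) -> Population:
    """Read a population snapshot CSV (columns id,x,y,state,cp)."""
    df = pd.read_csv(path)
    individuals = [
        Individual(
            id=int(row.id),
            position=Coordinate(float(row.x), float(row.y)),
            state=EpidemicState(row.state),
            overall_cp=float(row.cp),
        )
        for row in df.itertuples()
    ]
    return Population(individuals=individuals, epoch=0)
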