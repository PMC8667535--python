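"""Relocation strategies that minimize a social-distancing objective.

Every strategy answers the same question each epoch: where should each
individual stand next, subject to the hard movement bound ``tau``?

* ``sampling_epoch`` — Gibbs-style single-site relocation: nodes are
  visited one at a time in random order with all others held fixed; the
  best of K candidate locations (drawn uniformly in the tau-disk around
  the node's epoch-start position) is accepted only if it strictly lowers
  the global score.  Sweeps repeat until the fraction of nodes relocated
  in a sweep drops below the convergence index pi.
* ``grid_epoch`` — spatial map-reduce: the region is tiled into Z equal
  grids; each grid independently optimizes its member nodes inside its
  tau-padded bounds (map), then nodes whose final position lies in
  another grid's core are reassigned there (reduce).  Per-grid seeds are
  derived deterministically, so results do not depend on scheduling.
* ``hybrid_epoch`` — grids with the sampling optimizer and its
  convergence criterion inside each grid.
* ``distributed_schedule`` / ``distributed_epoch`` — each node waits for
  its lower-id contacts to move first and then relocates exactly once
  using only neighborhood knowledge; the waiting time equals the longest
  strictly-id-decreasing path ending at the node.
* ``apply_flouting`` — with probability phi a node ignores its
  recommendation and moves randomly instead.
* ``exhaustive_optimize`` — desk-scale brute-force joint optimum over a
  lattice of candidate positions; the oracle the scalable strategies are
  tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .contact_network import ContactNetwork
from .objectives import ObjectiveEvaluator, ObjectiveKind
from .population import Coordinate, Population, RegionSpec, random_move

__all__ = [
    "StrategyConfig",
    "GridSpec",
    "EpochOutcome",
    "propose_candidates",
    "sampling_epoch",
    "random_epoch",
    "grid_epoch",
    "hybrid_epoch",
    "distributed_schedule",
    "distributed_epoch",
    "apply_flouting",
    "exhaustive_optimize",
    "partition_grids",
    "assign_to_grid",
]

_STRATEGY_KINDS = ("random", "sampling", "grid", "hybrid", "distributed")


@dataclass(frozen=True)
class StrategyConfig:
    """Knobs of the relocation strategies.

    Parameters
    ----------
    kind:
        One of {random, sampling, grid, hybrid, distributed}.
    objective:
        The score being minimized.
    pi:
        Convergence index in (0, 1]: a sampling epoch ends when the
        fraction of nodes relocated in the last sweep falls below pi.
        Typical values 0.3-0.5.
    grid_count:
        Z, a perfect square; the region is tiled sqrt(Z) x sqrt(Z).
    candidates_per_node:
        K candidate locations probed per node visit (plus staying put).
    max_sweeps:
        Safety cap on sampling sweeps per epoch.
    flout_fraction:
        Probability that a node ignores its recommendation and moves
        randomly instead.
    seed:
        Base seed recorded for bookkeeping (drivers derive RNGs from it).
    """

    kind: str = "sampling"
    objective: ObjectiveKind = ObjectiveKind.DIRECT_CONTACT
    pi: float = 0.4
    grid_count: int = 1
    candidates_per_node: int = 10
    max_sweeps: int = 20
    flout_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _STRATEGY_KINDS:
            raise ValueError(f"unknown strategy kind: {self.kind!r}")
        if not 0.0 < self.pi <= 1.0:
            raise ValueError("convergence index pi must lie in (0, 1]")
        root = math.isqrt(self.grid_count)
        if self.grid_count < 1 or root * root != self.grid_count:
            raise ValueError("grid_count must be a perfect square >= 1")
        if self.candidates_per_node < 1:
            raise ValueError("candidates_per_node must be >= 1")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")
        if not 0.0 <= self.flout_fraction <= 1.0:
            raise ValueError("flout_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class GridSpec:
    """One tile of the spatial partition.

    ``core`` is the owned rectangle (x0, y0, x1, y1); cores tile the
    region exactly and are half-open on their upper edges except at the
    region's outer boundary.  ``padded`` extends the core by tau on every
    side, clipped to the region: during the map step a member node may
    stand anywhere inside the padded bounds, which hides the grid border
    from any node that cannot out-travel tau in one epoch.
    """

    row: int
    col: int
    core: tuple[float, float, float, float]
    padded: tuple[float, float, float, float]


@dataclass
class EpochOutcome:
    """Result of one strategy epoch: new positions plus bookkeeping."""

    positions: np.ndarray
    moved_fraction: float
    sweeps_used: int
    score_before: float
    score_after: float
    waiting_epochs: dict[int, int] | None = None
    grid_members: list[list[int]] | None = None

    @property
    def mean_wait(self) -> float | None:
        if self.waiting_epochs is None:
            return None
        if not self.waiting_epochs:
            return 0.0
        return sum(self.waiting_epochs.values()) / len(self.waiting_epochs)


# --------------------------------------------------------------------------
# candidate proposal


def _disk_samples(anchor: np.ndarray, tau: float, k: int, rng: np.random.Generator) -> np.ndarray:
    """(k, 2) array of uniform draws from the tau-disk around ``anchor``."""
    u = rng.random((k, 2))
    r = tau * np.sqrt(u[:, 0])
    theta = 2.0 * np.pi * u[:, 1]
    return anchor + np.column_stack((r * np.cos(theta), r * np.sin(theta)))


def _clip_box(points: np.ndarray, bounds: tuple[float, float, float, float]) -> np.ndarray:
    x0, y0, x1, y1 = bounds
    return np.column_stack(
        (np.clip(points[:, 0], x0, x1), np.clip(points[:, 1], y0, y1))
    )


def propose_candidates(
    position: Coordinate,
    tau: float,
    K: int,
    region: RegionSpec,
    rng: np.random.Generator,
) -> list[Coordinate]:
    """K uniform tau-disk candidates clipped to the region, plus staying put.

    Clipping to a box that contains the anchor can only shrink each
    displacement component, so every candidate is feasible (distance
    <= tau from ``position``).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    pts = _clip_box(
        _disk_samples(position.as_array(), tau, K, rng),
        (0.0, 0.0, region.X, region.Y),
    )
    return [Coordinate(float(x), float(y)) for x, y in pts] + [position]


# --------------------------------------------------------------------------
# the single-site sweep optimizer (shared by sampling / grid / hybrid)


def _sweep_optimize(
    ev: ObjectiveEvaluator,
    members: np.ndarray,
    anchors: np.ndarray,
    tau: float,
    bounds: tuple[float, float, float, float],
    pi: float,
    K: int,
    max_sweeps: int,
    rng: np.random.Generator,
) -> int:
    """Run convergence-bounded sweeps over ``members``; returns sweeps used.

    ``anchors`` are the epoch-start positions: every candidate is drawn
    in the tau-disk around the anchor (never the interim position), which
    enforces the per-epoch displacement bound no matter how many sweeps
    run.  A move is accepted only when it strictly lowers the score.
    """
    n_unit = len(members)
    sweeps = 0
    for _ in range(max_sweeps):
        sweeps += 1
        moved = 0
        order = rng.permutation(n_unit)
        for local in order:
            u = int(members[local])
            if not ev.live[u]:
                # recovered/dead nodes contribute nothing to any score,
                # so no candidate can strictly improve; skip the draws
                continue
            cands = _clip_box(_disk_samples(anchors[local], tau, K, rng), bounds)
            best_delta = 0.0
            best_pos = None
            best_row = None
            for pos in cands:
                delta, row = ev.move_delta(u, pos)
                if delta < best_delta - 1e-12:
                    best_delta, best_pos, best_row = delta, pos, row
            if best_pos is not None:
                ev.commit_move(u, best_pos, best_row)
                moved += 1
        if n_unit == 0 or moved / n_unit < pi:
            break
    return sweeps


def _make_evaluator(population: Population, region: RegionSpec, objective: ObjectiveKind) -> ObjectiveEvaluator:
    cp = population.cp_array() if objective is ObjectiveKind.CONTAGION_POTENTIAL else None
    return ObjectiveEvaluator(
        population.positions_array(),
        population.states_array(),
        region.d,
        objective,
        cp=cp,
    )


def sampling_epoch(
    population: Population,
    objective: ObjectiveKind,
    config: StrategyConfig,
    region: RegionSpec,
    rng: np.random.Generator,
) -> EpochOutcome:
    """One MCMC-style relocation epoch over the whole population."""
    ev = _make_evaluator(population, region, objective)
    score_before = ev.full_score()
    anchors = ev.pos.copy()
    members = np.arange(len(population))
    sweeps = _sweep_optimize(
        ev,
        members,
        anchors,
        region.tau,
        (0.0, 0.0, region.X, region.Y),
        config.pi,
        config.candidates_per_node,
        config.max_sweeps,
        rng,
    )
    moved = np.any(ev.pos != anchors, axis=1)
    return EpochOutcome(
        positions=ev.pos.copy(),
        moved_fraction=float(moved.mean()) if len(moved) else 0.0,
        sweeps_used=sweeps,
        score_before=float(score_before),
        score_after=float(ev.full_score()),
    )


def random_epoch(
    population: Population,
    objective: ObjectiveKind,
    config: StrategyConfig,
    region: RegionSpec,
    rng: np.random.Generator,
) -> EpochOutcome:
    """Unoptimized baseline: every node takes one random tau-bounded move."""
    ev = _make_evaluator(population, region, objective)
    score_before = ev.full_score()
    new_positions = ev.pos.copy()
    for i, ind in enumerate(population):
        pos = random_move(ind.position, region.tau, region, rng)
        new_positions[i] = (pos.x, pos.y)
    ev2 = ObjectiveEvaluator(new_positions, ev.states, region.d, objective, cp=ev.cp)
    return EpochOutcome(
        positions=new_positions,
        moved_fraction=1.0,
        sweeps_used=1,
        score_before=float(score_before),
        score_after=float(ev2.full_score()),
    )


# --------------------------------------------------------------------------
# grid partition


def partition_grids(region: RegionSpec, Z: int) -> list[GridSpec]:
    """Tile the region into sqrt(Z) x sqrt(Z) equal cores, each tau-padded."""
    root = math.isqrt(Z)
    if Z < 1 or root * root != Z:
        raise ValueError("grid count Z must be a perfect square >= 1")
    w, h = region.X / root, region.Y / root
    grids = []
    for row in range(root):
        for col in range(root):
            x0, y0 = col * w, row * h
            x1, y1 = x0 + w, y0 + h
            padded = (
                max(x0 - region.tau, 0.0),
                max(y0 - region.tau, 0.0),
                min(x1 + region.tau, region.X),
                min(y1 + region.tau, region.Y),
            )
            grids.append(GridSpec(row=row, col=col, core=(x0, y0, x1, y1), padded=padded))
    return grids


def assign_to_grid(position: Coordinate, grids: list[GridSpec]) -> int:
    """Index of the grid whose core owns ``position``.

    Cores are half-open on their upper edges; the region's outer boundary
    is closed, so positions on it fall to the last row/column.
    """
    root = math.isqrt(len(grids))
    w = grids[0].core[2] - grids[0].core[0]
    h = grids[0].core[3] - grids[0].core[1]
    col = min(int(position.x / w), root - 1)
    row = min(int(position.y / h), root - 1)
    return row * root + col


def grid_epoch(
    population: Population,
    objective: ObjectiveKind,
    config: StrategyConfig,
    region: RegionSpec,
    rng: np.random.Generator,
) -> EpochOutcome:
    """Map-reduce relocation epoch over Z spatial grids.

    Map: each grid runs the sweep optimizer over its own members only
    (its contact view is restricted to them), with candidates confined
    to the grid's padded bounds.  The grid problems are independent;
    per-grid RNGs are derived from integer seeds drawn once from the
    caller's generator, so any execution order gives identical results.
    With Z = 1 the single grid is the global problem and the caller's
    generator is used directly, making the epoch bit-identical to
    ``sampling_epoch``.

    Reduce: nodes whose final position lies in another grid's core are
    reassigned there; the returned ``grid_members`` is that final
    membership (a permutation of the population — nothing lost).
    """
    Z = config.grid_count
    grids = partition_grids(region, Z)
    ev = _make_evaluator(population, region, objective)
    score_before = ev.full_score()
    anchors = ev.pos.copy()

    members_by_grid: list[list[int]] = [[] for _ in grids]
    for i, ind in enumerate(population):
        members_by_grid[assign_to_grid(ind.position, grids)].append(i)

    if Z == 1:
        grid_rngs = [rng]
    else:
        seeds = rng.integers(0, 2**31 - 1, size=Z)
        grid_rngs = [np.random.default_rng(int(s)) for s in seeds]

    states = ev.states
    cp = ev.cp
    new_positions = anchors.copy()
    sweeps_max = 0
    for g, grid in enumerate(grids):
        members = np.array(members_by_grid[g], dtype=int)
        if members.size == 0:
            continue
        sub_cp = cp[members] if cp is not None else None
        sub_ev = ObjectiveEvaluator(
            anchors[members], states[members], region.d, objective, cp=sub_cp
        )
        sweeps = _sweep_optimize(
            sub_ev,
            np.arange(members.size),
            anchors[members],
            region.tau,
            grid.padded,
            config.pi,
            config.candidates_per_node,
            config.max_sweeps,
            grid_rngs[g],
        )
        sweeps_max = max(sweeps_max, sweeps)
        new_positions[members] = sub_ev.pos

    # reduce: recompute ownership from the final positions
    final_members: list[list[int]] = [[] for _ in grids]
    for i, (x, y) in enumerate(new_positions):
        final_members[assign_to_grid(Coordinate(float(x), float(y)), grids)].append(i)

    ev_after = ObjectiveEvaluator(new_positions, states, region.d, objective, cp=cp)
    moved = np.any(new_positions != anchors, axis=1)
    return EpochOutcome(
        positions=new_positions,
        moved_fraction=float(moved.mean()) if len(moved) else 0.0,
        sweeps_used=sweeps_max,
        score_before=float(score_before),
        score_after=float(ev_after.full_score()),
        grid_members=final_members,
    )


def hybrid_epoch(
    population: Population,
    objective: ObjectiveKind,
    config: StrategyConfig,
    region: RegionSpec,
    rng: np.random.Generator,
) -> EpochOutcome:
    """Grid partitioning with the sampling optimizer (and its convergence
    index) inside every grid, then the usual reduce step.

    The map step of ``grid_epoch`` already runs the single-site sampler
    within each grid's padded bounds, so the hybrid coincides with it;
    both entry points are kept because they are configured differently
    (the hybrid requires both pi and Z to be meaningful).
    """
    return grid_epoch(population, objective, config, region, rng)


# --------------------------------------------------------------------------
# distributed scheduling


def distributed_schedule(network: ContactNetwork) -> tuple[list[list[int]], dict[int, int]]:
    """Micro-round move order under the lower-id-first rule.

    A node may move in the first micro-round in which all of its lower-id
    contacts have already moved, so its waiting time equals the length of
    the longest strictly-id-decreasing path ending at it.  Returns the
    rounds (each a sorted list of ids) and the per-node waiting count.
    """
    waiting: dict[int, int] = {}
    for u in sorted(network.graph.nodes):
        lower = [v for v in network.graph.neighbors(u) if v < u]
        waiting[u] = 1 + max(waiting[v] for v in lower) if lower else 0
    n_rounds = max(waiting.values(), default=-1) + 1
    rounds: list[list[int]] = [[] for _ in range(n_rounds)]
    for u, r in waiting.items():
        rounds[r].append(u)
    for r in rounds:
        r.sort()
    return rounds, waiting


def distributed_epoch(
    population: Population,
    objective: ObjectiveKind,
    config: StrategyConfig,
    region: RegionSpec,
    rng: np.random.Generator,
) -> EpochOutcome:
    """Decentralized epoch: every node relocates exactly once, in
    micro-round order, accepting the best strictly-improving candidate.

    The acceptance test only involves edges and triangles through the
    moving node, so each node needs nothing beyond its own neighborhood —
    the global score is used here purely as bookkeeping.
    """
    ev = _make_evaluator(population, region, objective)
    score_before = ev.full_score()
    anchors = ev.pos.copy()
    ids = [ind.id for ind in population]
    index_of = {nid: i for i, nid in enumerate(ids)}
    network = ContactNetwork.from_positions(ids, anchors, region.d, epoch=population.epoch)
    rounds, waiting = distributed_schedule(network)

    bounds = (0.0, 0.0, region.X, region.Y)
    moved = 0
    for micro_round in rounds:
        for nid in micro_round:
            u = index_of[nid]
            if not ev.live[u]:
                continue
            cands = _clip_box(
                _disk_samples(anchors[u], region.tau, config.candidates_per_node, rng),
                bounds,
            )
            best_delta, best_pos, best_row = 0.0, None, None
            for pos in cands:
                delta, row = ev.move_delta(u, pos)
                if delta < best_delta - 1e-12:
                    best_delta, best_pos, best_row = delta, pos, row
            if best_pos is not None:
                ev.commit_move(u, best_pos, best_row)
                moved += 1
    return EpochOutcome(
        positions=ev.pos.copy(),
        moved_fraction=moved / len(population) if len(population) else 0.0,
        sweeps_used=1,
        score_before=float(score_before),
        score_after=float(ev.full_score()),
        waiting_epochs=waiting,
    )


# --------------------------------------------------------------------------
# flouting overlay


def apply_flouting(
    recommended: np.ndarray,
    current: np.ndarray,
    phi: float,
    tau: float,
    region: RegionSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Each node independently ignores its recommendation with probability
    ``phi`` and performs a random tau-bounded move from its current
    position instead."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError("flout probability must lie in [0, 1]")
    recommended = np.asarray(recommended, dtype=float)
    current = np.asarray(current, dtype=float)
    out = recommended.copy()
    flout = rng.random(len(current)) < phi
    for i in np.nonzero(flout)[0]:
        pos = random_move(Coordinate(*current[i]), tau, region, rng)
        out[i] = (pos.x, pos.y)
    return out


# --------------------------------------------------------------------------
# desk-scale exhaustive oracle


def exhaustive_optimize(
    population: Population,
    objective: ObjectiveKind,
    d: float,
    tau: float,
    resolution: int = 5,
    region: RegionSpec | None = None,
) -> tuple[np.ndarray, float]:
    """Joint brute-force optimum over a lattice of candidate positions.

    Each node's candidates are the points of a resolution x resolution
    lattice spanning its tau-disk (plus its current spot when the lattice
    center hits it), clipped to the region; the full product space is
    scored and the minimizing assignment returned.  Only viable for tiny
    populations — this is the oracle the scalable strategies are measured
    against, not a production path.

    Returns (positions, score).
    """
    n = len(population)
    if n > 6:
        raise ValueError("exhaustive optimization is limited to populations of <= 6")
    if region is None:
        region = RegionSpec(X=math.inf, Y=math.inf, d=d, tau=tau)

    anchors = population.positions_array()
    states = population.states_array()
    cp_all = population.cp_array()

    offsets = np.linspace(-tau, tau, resolution)
    ox, oy = np.meshgrid(offsets, offsets)
    grid_offsets = np.column_stack((ox.ravel(), oy.ravel()))
    grid_offsets = grid_offsets[np.hypot(grid_offsets[:, 0], grid_offsets[:, 1]) <= tau + 1e-9]

    cand_sets = []
    for i in range(n):
        pts = _clip_box(anchors[i] + grid_offsets, (0.0, 0.0, region.X, region.Y))
        cand_sets.append(np.unique(pts, axis=0))
    counts = [len(c) for c in cand_sets]
    total = math.prod(counts)
    if total > 2_000_000:
        raise ValueError(f"lattice product space too large ({total} assignments)")

    idx = np.stack(
        np.meshgrid(*[np.arange(c) for c in counts], indexing="ij"), axis=0
    ).reshape(n, -1)
    # (total, n, 2) positions for every joint assignment
    pos = np.stack([cand_sets[i][idx[i]] for i in range(n)], axis=1)

    se = (states == 0) | (states == 1)
    inf = states == 2
    live = se | inf

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    adj = {}
    for i, j in pairs:
        dist2 = np.sum((pos[:, i] - pos[:, j]) ** 2, axis=1)
        adj[(i, j)] = dist2 <= d * d

    scores = np.zeros(total)
    if objective is ObjectiveKind.DIRECT_CONTACT:
        for i, j in pairs:
            if (se[i] and inf[j]) or (inf[i] and se[j]):
                scores += adj[(i, j)]
    elif objective is ObjectiveKind.CONTAGION_POTENTIAL:
        for i, j in pairs:
            if live[i] and live[j]:
                scores += adj[(i, j)] * abs(cp_all[i] - cp_all[j])
    else:
        for i in range(n):
            for j in range(i + 1, n):
                for k in range(j + 1, n):
                    trio_live = live[i] and live[j] and live[k]
                    has_se = se[i] or se[j] or se[k]
                    has_i = inf[i] or inf[j] or inf[k]
                    if trio_live and has_se and has_i:
                        scores += adj[(i, j)] & adj[(j, k)] & adj[(i, k)]

    best = int(np.argmin(scores))
    return pos[best].copy(), float(scores[best])
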