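import numpy as np
import pytest

from socdist import (
    ContactNetwork,
    Coordinate,
    EpidemicState,
    ObjectiveKind,
    RegionSpec,
    StrategyConfig,
    apply_flouting,
    assign_to_grid,
    distributed_epoch,
    distributed_schedule,
    exhaustive_optimize,
    generate_population,
    grid_epoch,
    hybrid_epoch,
    partition_grids,
    propose_candidates,
    sampling_epoch,
)

from conftest import make_population

DC = ObjectiveKind.DIRECT_CONTACT


class TestStrategyConfig:
    def test_defaults_valid(self):
        cfg = StrategyConfig()
        assert cfg.pi == 0.4 and cfg.grid_count == 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kind": "teleport"},
            {"pi": 0.0},
            {"pi": 1.5},
            {"grid_count": 5},
            {"grid_count": 0},
            {"candidates_per_node": 0},
            {"flout_fraction": 1.2},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StrategyConfig(**kwargs)


class TestProposeCandidates:
    def test_zero_tau_collapses_to_stay(self, region, rng):
        cands = propose_candidates(Coordinate(10, 10), 0.0, 5, region, rng)
        assert all(c == Coordinate(10, 10) for c in cands)

    def test_count_includes_stay_option(self, region, rng):
        cands = propose_candidates(Coordinate(10, 10), 25.0, 5, region, rng)
        assert len(cands) == 6
        assert Coordinate(10, 10) in cands

    def test_every_candidate_feasible_and_inside(self, region, rng):
        start = Coordinate(3.0, 97.0)
        for _ in range(100):
            for c in propose_candidates(start, 25.0, 8, region, rng):
                assert region.contains(c)
                assert start.distance_to(c) <= 25.0 + 1e-9


class TestSamplingEpoch:
    def test_zero_score_means_no_moves(self, region, rng):
        pop = make_population([(0, 0, "S"), (50, 50, "S"), (90, 90, "S")])
        out = sampling_epoch(pop, DC, StrategyConfig(), region, rng)
        assert out.score_before == 0.0
        assert out.score_after == 0.0
        assert out.moved_fraction == 0.0
        assert out.sweeps_used == 1

    def test_separates_close_si_pair(self, region):
        # tau=25 >> d=6: a separating candidate exists with high probability
        for seed in range(10):
            pop = make_population([(50, 50, "S"), (53, 50, "I")])
            cfg = StrategyConfig(candidates_per_node=50)
            out = sampling_epoch(pop, DC, cfg, region, np.random.default_rng(seed))
            assert out.score_before == 1.0
            assert out.score_after == 0.0

    def test_score_never_increases(self, region):
        for seed in range(10):
            pop = generate_population(40, region, seed=seed)
            out = sampling_epoch(pop, DC, StrategyConfig(), region, np.random.default_rng(seed))
            assert out.score_after <= out.score_before

    def test_displacements_bounded_by_tau(self, region):
        for seed in range(5):
            pop = generate_population(40, region, seed=seed)
            start = pop.positions_array()
            out = sampling_epoch(
                pop, DC, StrategyConfig(max_sweeps=20), region, np.random.default_rng(seed)
            )
            disp = np.hypot(*(out.positions - start).T)
            assert disp.max() <= region.tau + 1e-9

    def test_does_not_mutate_population(self, region, rng):
        pop = generate_population(20, region, seed=0)
        before = pop.positions_array()
        sampling_epoch(pop, DC, StrategyConfig(), region, rng)
        assert np.array_equal(pop.positions_array(), before)

    @pytest.mark.parametrize("kind", list(ObjectiveKind))
    def test_all_objectives_runnable(self, region, kind):
        pop = generate_population(30, region, seed=1)
        out = sampling_epoch(pop, kind, StrategyConfig(), region, np.random.default_rng(1))
        assert out.score_after <= out.score_before


class TestExhaustiveOracle:
    def test_two_node_si_pair_reaches_zero(self, region):
        pop = make_population([(50, 50, "S"), (53, 50, "I")])
        _, best = exhaustive_optimize(pop, DC, d=6.0, tau=25.0, resolution=5, region=region)
        assert best == 0.0

    def test_all_susceptible_scores_zero(self, region):
        pop = make_population([(50, 50, "S"), (52, 50, "S"), (54, 50, "S")])
        _, best = exhaustive_optimize(pop, DC, d=6.0, tau=25.0, resolution=3, region=region)
        assert best == 0.0

    def test_sampling_never_beats_oracle_at_zero(self, region):
        pop = make_population([(50, 50, "S"), (53, 50, "I"), (47, 50, "S")])
        _, oracle = exhaustive_optimize(pop, DC, d=6.0, tau=25.0, resolution=5, region=region)
        assert oracle == 0.0
        out = sampling_epoch(
            pop, DC, StrategyConfig(candidates_per_node=50), region, np.random.default_rng(0)
        )
        assert out.score_after >= oracle

    def test_population_size_capped(self, region):
        pop = generate_population(7, region, seed=0)
        with pytest.raises(ValueError):
            exhaustive_optimize(pop, DC, d=6.0, tau=25.0, region=region)

    def test_unavoidable_contact_floor(self):
        # region diameter (4*sqrt(2) ~ 5.66) below d: every pair is always
        # in contact, so both S-I edges survive any relocation
        small = RegionSpec(X=4.0, Y=4.0, d=6.0, tau=3.0)
        pop = make_population([(1, 2, "S"), (2, 2, "I"), (3, 2, "S")])
        _, best = exhaustive_optimize(pop, DC, d=6.0, tau=3.0, resolution=3, region=small)
        assert best == 2.0


class TestGridPartition:
    def test_four_grids_tile_region(self, region):
        grids = partition_grids(region, 4)
        assert len(grids) == 4
        for g in grids:
            x0, y0, x1, y1 = g.core
            assert (x1 - x0, y1 - y0) == (50.0, 50.0)
        assert {g.core[:2] for g in grids} == {(0, 0), (50, 0), (0, 50), (50, 50)}

    def test_single_grid_covers_region(self, region):
        (g,) = partition_grids(region, 1)
        assert g.core == (0.0, 0.0, 100.0, 100.0)
        assert g.padded == (0.0, 0.0, 100.0, 100.0)

    def test_padding_extends_by_tau_clipped(self, region):
        grids = partition_grids(region, 4)
        g00 = next(g for g in grids if g.core[:2] == (0, 0))
        assert g00.padded == (0.0, 0.0, 75.0, 75.0)

    def test_non_square_count_rejected(self, region):
        with pytest.raises(ValueError):
            partition_grids(region, 6)

    @pytest.mark.parametrize(
        "point, expected_core",
        [
            ((51, 10), (50, 0)),    # right-bottom
            ((50, 50), (50, 50)),   # internal border: upper-right by half-open rule
            ((100, 100), (50, 50)),  # outer boundary closed
            ((10, 10), (0, 0)),
        ],
    )
    def test_assign_to_grid(self, region, point, expected_core):
        grids = partition_grids(region, 4)
        idx = assign_to_grid(Coordinate(*point), grids)
        assert grids[idx].core[:2] == expected_core


class TestGridEpoch:
    def test_degenerate_single_grid_bit_identical_to_sampling(self, region):
        cfg = StrategyConfig(kind="grid", grid_count=1)
        for seed in range(5):
            pop = generate_population(40, region, seed=seed)
            a = sampling_epoch(pop, DC, cfg, region, np.random.default_rng(seed))
            b = grid_epoch(pop, DC, cfg, region, np.random.default_rng(seed))
            assert np.array_equal(a.positions, b.positions)
            assert a.score_after == b.score_after

    def test_membership_is_permutation(self, region):
        cfg = StrategyConfig(kind="grid", grid_count=4)
        pop = generate_population(60, region, seed=2)
        out = grid_epoch(pop, DC, cfg, region, np.random.default_rng(2))
        flat = sorted(i for members in out.grid_members for i in members)
        assert flat == list(range(60))

    def test_reduce_reassigns_border_crosser(self, region):
        grids = partition_grids(region, 4)
        # node anchored near the internal border inside grid (0,0)
        pop = make_population([(49, 10, "S"), (52, 10, "I")])
        cfg = StrategyConfig(kind="grid", grid_count=4, candidates_per_node=50)
        out = grid_epoch(pop, DC, cfg, region, np.random.default_rng(0))
        for members, grid in zip(out.grid_members, grids):
            for i in members:
                x, y = out.positions[i]
                assert assign_to_grid(Coordinate(float(x), float(y)), grids) == grids.index(grid)

    def test_displacement_bound_and_score_monotone(self, region):
        for z in (4, 9):
            for seed in range(3):
                pop = generate_population(50, region, seed=seed)
                start = pop.positions_array()
                cfg = StrategyConfig(kind="grid", grid_count=z)
                out = grid_epoch(pop, DC, cfg, region, np.random.default_rng(seed))
                disp = np.hypot(*(out.positions - start).T)
                assert disp.max() <= region.tau + 1e-9

    def test_map_step_confined_to_padded_bounds(self, region):
        grids = partition_grids(region, 4)
        pop = generate_population(60, region, seed=5)
        start_grid = [assign_to_grid(ind.position, grids) for ind in pop]
        cfg = StrategyConfig(kind="grid", grid_count=4)
        out = grid_epoch(pop, DC, cfg, region, np.random.default_rng(5))
        for i, g in enumerate(start_grid):
            x0, y0, x1, y1 = grids[g].padded
            x, y = out.positions[i]
            assert x0 - 1e-9 <= x <= x1 + 1e-9
            assert y0 - 1e-9 <= y <= y1 + 1e-9

    def test_hybrid_degenerate_equals_sampling(self, region):
        cfg = StrategyConfig(kind="hybrid", grid_count=1)
        pop = generate_population(30, region, seed=7)
        a = sampling_epoch(pop, DC, cfg, region, np.random.default_rng(7))
        b = hybrid_epoch(pop, DC, cfg, region, np.random.default_rng(7))
        assert np.array_equal(a.positions, b.positions)


class TestDistributed:
    def test_isolated_node_waits_zero(self):
        net = ContactNetwork.from_edges([], nodes=[0])
        _, waiting = distributed_schedule(net)
        assert waiting[0] == 0

    def test_ascending_path_waits_accumulate(self):
        net = ContactNetwork.from_edges([(1, 2), (2, 3)])
        rounds, waiting = distributed_schedule(net)
        assert waiting == {1: 0, 2: 1, 3: 2}
        assert rounds == [[1], [2], [3]]

    def test_rounds_respect_lower_id_precedence(self):
        rng = np.random.default_rng(8)
        n = 30
        edges = [(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.15]
        net = ContactNetwork.from_edges(edges, nodes=range(n))
        rounds, waiting = distributed_schedule(net)
        scheduled = {}
        for r, batch in enumerate(rounds):
            for u in batch:
                scheduled[u] = r
        for u, v in edges:
            lo, hi = min(u, v), max(u, v)
            assert scheduled[lo] < scheduled[hi]

    def test_mean_wait_grows_with_density(self, region):
        # fixed area, growing population: longer decreasing-id chains
        means = []
        for n in (25, 50, 75, 100):
            waits = []
            for seed in range(10):
                pop = generate_population(n, region, seed=seed)
                net = ContactNetwork.from_positions(
                    range(n), pop.positions_array(), region.d
                )
                _, waiting = distributed_schedule(net)
                waits.append(np.mean(list(waiting.values())))
            means.append(np.mean(waits))
        assert means == sorted(means)
        assert means[0] < means[-1]

    def test_distributed_epoch_improves_and_reports_waits(self, region):
        pop = generate_population(50, region, seed=3)
        out = distributed_epoch(pop, DC, StrategyConfig(), region, np.random.default_rng(3))
        assert out.score_after <= out.score_before
        assert out.waiting_epochs is not None and len(out.waiting_epochs) == 50
        assert out.mean_wait >= 0.0


class TestFlouting:
    def test_phi_zero_keeps_recommendations(self, region, rng):
        rec = np.array([[1.0, 1.0], [2.0, 2.0]])
        cur = np.array([[5.0, 5.0], [6.0, 6.0]])
        out = apply_flouting(rec, cur, 0.0, 25.0, region, rng)
        assert np.array_equal(out, rec)

    def test_phi_one_randomizes_all_from_current(self, region, rng):
        rec = np.array([[1.0, 1.0], [2.0, 2.0]])
        cur = np.array([[50.0, 50.0], [60.0, 60.0]])
        out = apply_flouting(rec, cur, 1.0, 25.0, region, rng)
        disp = np.hypot(*(out - cur).T)
        assert np.all(disp <= 25.0 + 1e-9)
        assert not np.array_equal(out, rec)

    def test_flouter_count_is_binomial(self, region):
        rng = np.random.default_rng(99)
        n = 1000
        rec = np.full((n, 2), 10.0)
        cur = np.full((n, 2), 80.0)
        out = apply_flouting(rec, cur, 0.3, 25.0, region, rng)
        flouted = np.count_nonzero(np.any(out != rec, axis=1))
        sd = np.sqrt(n * 0.3 * 0.7)
        assert abs(flouted - 300) <= 3 * sd
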