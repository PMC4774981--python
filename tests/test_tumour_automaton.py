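"""Cellular automaton: phenotype switching, division, migration, clearance."""

import numpy as np
import pytest

from gliosim.config import ChemConstants, LatticeSpec, NetworkGenParams, PhenotypeParams
from gliosim.fixtures import small_tree_network
from gliosim.tumour_automaton import (EC, EMPTY, M, N, P, Q, CellGrid,
                                      SeedingError, phenotype_sources,
                                      seed_initial_cells, step_cells,
                                      vessel_adjacency)


@pytest.fixture
def phen():
    return PhenotypeParams()


def make_grid(n=20):
    return CellGrid(LatticeSpec(n, n, n, 10.0))


def co_field(grid, value):
    return np.full(grid.lattice.n_nodes, value)


class TestPhenotypeSwitching:
    def test_ripe_cell_with_space_divides_surely(self, phen, rng):
        """T_age = T_TC, high oxygen, free neighbour: division probability 1."""
        grid = make_grid(9)
        node = grid.lattice.ravel(4, 4, 4)
        grid.occupant[node] = P
        grid.age[node] = phen.T_TC          # stays at cap after increment
        ev = step_cells(grid, co_field(grid, 0.9), phen, rng)
        assert ev.divisions == 1
        assert (grid.occupant == P).sum() == 2

    def test_any_phenotype_below_survival_threshold_necroses(self, phen, rng):
        grid = make_grid(9)
        nodes = [grid.lattice.ravel(2, 2, 2), grid.lattice.ravel(6, 6, 6),
                 grid.lattice.ravel(2, 6, 2)]
        for nd, code in zip(nodes, (P, Q, M)):
            grid.occupant[nd] = code
        ev = step_cells(grid, co_field(grid, 0.01), phen, rng)
        assert ev.to_necrotic == 3
        assert all(grid.occupant[nd] == N for nd in nodes)

    def test_crowded_cell_goes_quiescent_and_returns(self, phen, rng):
        grid = make_grid(9)
        centre = grid.lattice.ravel(4, 4, 4)
        grid.occupant[centre] = P
        grid.age[centre] = 3
        for nb in grid.neighbours[centre]:
            grid.occupant[nb] = N
        step_cells(grid, co_field(grid, 0.9), phen, rng)
        assert grid.occupant[centre] == Q
        # free one neighbour: quiescent cell resumes proliferation
        grid.occupant[grid.neighbours[centre][0]] = EMPTY
        ev = step_cells(grid, co_field(grid, 0.9), phen, rng)
        assert grid.occupant[centre] in (P, Q)  # sweep order may divide first
        assert ev.from_quiescent >= 0
        # with certainty after a step where nothing else interferes
        grid2 = make_grid(9)
        c2 = grid2.lattice.ravel(4, 4, 4)
        grid2.occupant[c2] = Q
        ev2 = step_cells(grid2, co_field(grid2, 0.9), phen, rng)
        assert grid2.occupant[c2] == P
        assert ev2.from_quiescent == 1

    def test_migrating_settles_at_rich_oxygen(self, phen, rng):
        grid = make_grid(9)
        node = grid.lattice.ravel(4, 4, 4)
        grid.occupant[node] = M
        step_cells(grid, co_field(grid, 0.5), phen, rng)
        assert grid.occupant[node] == P

    def test_migration_frees_origin_and_tracks_oxygen(self, phen, rng):
        grid = make_grid(9)
        lat = grid.lattice
        node = lat.ravel(4, 4, 4)
        grid.occupant[node] = M
        co = np.zeros(lat.shape)
        co[:, :, :] = 0.08
        co[5, 4, 4] = 0.14          # best neighbour, still below theta_prol
        ev = step_cells(grid, co.ravel(), phen, rng)
        assert ev.migrations == 1
        assert grid.occupant[node] == EMPTY
        assert grid.occupant[lat.ravel(5, 4, 4)] == M


class TestStochasticRates:
    def test_migration_frequency_half(self, phen):
        """Isolated P cells at intermediate oxygen convert to M at 0.5,
        within 3 sigma of binomial over ~1e5 trials."""
        rng = np.random.default_rng(7)
        n_trials = 0
        conversions = 0
        lat = LatticeSpec(51, 51, 51, 10.0)
        for rep in range(10):
            grid = CellGrid(lat)
            idx = np.arange(lat.n_nodes).reshape(lat.shape)
            cells = idx[1:-1:3, 1:-1:3, 1:-1:3].ravel()  # isolated, spaced
            grid.occupant[cells] = P
            grid.age[cells] = 1
            ev = step_cells(grid, np.full(lat.n_nodes, 0.10), phen, rng)
            n_trials += len(cells)
            conversions += ev.to_migrating
        p_hat = conversions / n_trials
        sigma = np.sqrt(0.5 * 0.5 / n_trials)
        assert abs(p_hat - 0.5) < 3 * sigma

    def test_necrotic_clearance_frequency(self, phen):
        """N cells past the 30-step delay clear at 0.2 per step."""
        rng = np.random.default_rng(8)
        lat = LatticeSpec(50, 50, 50, 10.0)
        grid = CellGrid(lat)
        grid.occupant[:] = N
        grid.necrotic_steps[:] = 31
        ev = step_cells(grid, np.zeros(lat.n_nodes), phen, rng)
        n = lat.n_nodes
        p_hat = ev.cleared / n
        sigma = np.sqrt(0.2 * 0.8 / n)
        assert abs(p_hat - 0.2) < 3 * sigma

    def test_no_clearance_before_delay(self, phen, rng):
        grid = make_grid(10)
        grid.occupant[:] = N
        grid.necrotic_steps[:] = 5
        ev = step_cells(grid, co_field(grid, 0.0), phen, rng)
        assert ev.cleared == 0

    def test_division_rate_matches_age_ladder_expectation(self, phen):
        """Expected divisions for isolated ripe cells = sum of age/T_TC."""
        rng = np.random.default_rng(9)
        lat = LatticeSpec(40, 40, 40, 10.0)
        grid = CellGrid(lat)
        idx = np.arange(lat.n_nodes).reshape(lat.shape)
        cells = idx[1:-1:3, 1:-1:3, 1:-1:3].ravel()
        ages = rng.integers(1, phen.T_TC + 1, len(cells))
        grid.occupant[cells] = P
        grid.age[cells] = ages
        ev = step_cells(grid, np.full(lat.n_nodes, 0.9), phen, rng)
        # ages increment before the division draw (capped at T_TC)
        p = np.minimum(ages + 1, phen.T_TC) / phen.T_TC
        expect = p.sum()
        sigma = np.sqrt((p * (1 - p)).sum())
        assert abs(ev.divisions - expect) < 4 * sigma + 1

    def test_hypoxic_population_decays_geometrically(self, phen):
        """All cells necrose in one step under lethal hypoxia, then decay
        at the clearance rate once past the delay."""
        rng = np.random.default_rng(10)
        grid = make_grid(12)
        idx = np.arange(grid.lattice.n_nodes)
        cells = idx[:: 7]
        grid.occupant[cells] = P
        co = co_field(grid, 0.0)
        step_cells(grid, co, phen, rng)
        assert (grid.occupant[cells] == N).all()
        for _ in range(phen.clearance_delay):
            step_cells(grid, co, phen, rng)
        n0 = (grid.occupant == N).sum()
        survivors = []
        for _ in range(5):
            step_cells(grid, co, phen, rng)
            survivors.append((grid.occupant == N).sum())
        expect = n0 * (1 - phen.p_necrotic_clear) ** np.arange(1, 6)
        assert np.allclose(survivors, expect, rtol=0.25)


class TestBookkeeping:
    def test_count_deltas_explained_by_events(self, phen):
        rng = np.random.default_rng(11)
        grid = make_grid(16)
        lat = grid.lattice
        blob = np.arange(lat.n_nodes).reshape(lat.shape)[5:11, 5:11, 5:11].ravel()
        grid.occupant[blob] = rng.choice([P, Q, N, M], len(blob), p=[.4, .3, .2, .1])
        grid.age[np.flatnonzero(grid.occupant == P)] = 3
        grid.necrotic_steps[np.flatnonzero(grid.occupant == N)] = 20
        co = rng.uniform(0, 1, lat.n_nodes)
        co /= co.max()
        before = grid.counts()
        ev = step_cells(grid, co, phen, rng)
        after = grid.counts()
        assert after["total"] - before["total"] == ev.divisions - ev.cleared
        assert after["N"] - before["N"] == ev.to_necrotic - ev.cleared

    def test_single_occupancy_invariant(self, phen):
        rng = np.random.default_rng(12)
        grid = make_grid(14)
        lat = grid.lattice
        blob = np.arange(lat.n_nodes).reshape(lat.shape)[4:10, 4:10, 4:10].ravel()
        grid.occupant[blob] = P
        grid.age[blob] = 2
        co = np.full(lat.n_nodes, 0.5)
        for _ in range(5):
            step_cells(grid, co, phen, rng)
        assert set(np.unique(grid.occupant)) <= {EMPTY, P, Q, N, M, EC}

    def test_contract_violation_on_bad_oxygen(self, phen, rng):
        grid = make_grid(8)
        with pytest.raises(ValueError):
            step_cells(grid, co_field(grid, 1.5), phen, rng)


class TestSeeding:
    def test_default_seeding_near_order1(self, phen):
        net = small_tree_network(n=26)
        grid = CellGrid(net.lattice)
        rng = np.random.default_rng(13)
        seeded = seed_initial_cells(grid, net, 20, "perfusion_rich", rng, phen)
        assert len(seeded) == 20
        assert (grid.occupant[seeded] == P).all()
        assert grid.age[seeded].min() >= 1
        assert grid.age[seeded].max() <= phen.T_TC
        # all within one node of an order-1 capillary path
        order1 = np.unique(np.concatenate(
            [s.node_path for s in net.segments if s.order == 1]))
        lat = net.lattice
        o1_xyz = np.array([lat.coords(int(x)) for x in order1])
        for nd in seeded:
            d = np.linalg.norm(o1_xyz - np.array(lat.coords(int(nd))), axis=1)
            assert d.min() <= 3 * lat.spacing

    def test_zero_cells_unchanged(self, phen, rng):
        net = small_tree_network(n=26)
        grid = CellGrid(net.lattice)
        seeded = seed_initial_cells(grid, net, 0, "perfusion_rich", rng, phen)
        assert len(seeded) == 0
        assert (grid.occupant == EMPTY).all()

    def test_fixed_seed_identical_placement(self, phen):
        net = small_tree_network(n=26)
        outs = []
        for _ in range(2):
            grid = CellGrid(net.lattice)
            rng = np.random.default_rng(99)
            outs.append(seed_initial_cells(grid, net, 20, "perfusion_poor",
                                           rng, phen))
        assert np.array_equal(outs[0], outs[1])

    def test_poor_placement_sparser_than_rich(self, phen):
        net = small_tree_network(n=26)
        lat = net.lattice
        coords = np.array([lat.coords(int(x)) for x in net.path_nodes()])
        centroids = {}
        for mode in ("perfusion_rich", "perfusion_poor"):
            grid = CellGrid(lat)
            rng = np.random.default_rng(5)
            seeded = seed_initial_cells(grid, net, 20, mode, rng, phen)
            xyz = np.array([lat.coords(int(x)) for x in seeded]).mean(axis=0)
            d = np.linalg.norm(coords - xyz, axis=1)
            centroids[mode] = np.sort(d)[:50].mean()
        assert centroids["perfusion_poor"] > centroids["perfusion_rich"]

    def test_explicit_needs_enough_nodes(self, phen, rng):
        net = small_tree_network(n=26)
        grid = CellGrid(net.lattice)
        with pytest.raises(SeedingError):
            seed_initial_cells(grid, net, 5, "explicit", rng, phen,
                               explicit_nodes=[1, 2])


class TestPhenotypeSources:
    @pytest.mark.parametrize("code,name,mde,vegf,o2", [
        (M, "M", 2.0, 4.0, 2.0),
        (P, "P", 1.0, 1.0, 1.0),
        (Q, "Q", 0.2, 2.0, 0.5),
        (N, "N", 0.1, 4.0, 0.25),
    ])
    def test_per_phenotype_multipliers(self, chem, phen, code, name, mde, vegf, o2):
        grid = make_grid(6)
        node = 17
        grid.occupant[node] = code
        m, v, vs, g = phenotype_sources(grid, chem, phen)
        assert m[node] == pytest.approx(chem.mu_T * mde)
        assert v[node] == pytest.approx(chem.chi * vegf)
        assert g[node] == pytest.approx(chem.gamma0 * o2)

    def test_empty_node_all_zero(self, chem, phen):
        grid = make_grid(6)
        m, v, vs, g = phenotype_sources(grid, chem, phen)
        assert m.sum() == v.sum() == vs.sum() == g.sum() == 0.0

    def test_endothelial_cells_make_mde_and_consume_vegf(self, chem, phen):
        grid = make_grid(6)
        grid.occupant[4] = EC
        m, v, vs, g = phenotype_sources(grid, chem, phen)
        assert m[4] == pytest.approx(chem.mu_E)
        assert vs[4] == pytest.approx(chem.eps_ec)
        assert g[4] == 0.0

    def test_quiescent_vegf_twice_proliferating(self, chem, phen):
        grid = make_grid(6)
        grid.occupant[3] = P
        grid.occupant[9] = Q
        _, v, _, _ = phenotype_sources(grid, chem, phen)
        assert v[9] == pytest.approx(2 * v[3])


class TestVesselAdjacency:
    def test_flags_and_axis(self):
        net = small_tree_network(n=26)
        grid = CellGrid(net.lattice)
        adj, axis = vessel_adjacency(net, grid)
        path = net.segments[0].node_path
        assert adj[np.asarray(path)].all()
        assert (axis[np.asarray(path)] >= 0).all()
        far = net.lattice.ravel(25, 25, 25)
        # the far corner is not adjacent unless a vessel runs there
        vessel_nodes = set(int(x) for x in net.path_nodes())
        if far not in vessel_nodes:
            nb_far = grid.neighbours[far]
            if not any(int(x) in vessel_nodes for x in nb_far if x >= 0):
                assert not adj[far]
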