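"""Co-option, wall remodelling laws, WSS collapse and sprout kinetics."""

import numpy as np
import pytest

from gliosim.config import LatticeSpec, RemodellingParams
from gliosim.fixtures import single_segment_network, small_tree_network
from gliosim.tumour_automaton import EMPTY, P, CellGrid
from gliosim.vessel_remodelling import (SproutTip, angiogenesis_step,
                                        co_opt_and_dilate, collapse_check,
                                        collapse_segment,
                                        segment_tumour_fraction,
                                        tip_move_weights,
                                        update_collapse_pressure,
                                        update_permeability,
                                        update_radius_compliance)


def make_segment(maturity="immature", R=6.0, R0=6.0, order=2):
    net = single_segment_network(n=9, radius=R)
    seg = net.segments[0]
    seg.maturity = maturity
    seg.R, seg.R0, seg.order = R, R0, order
    seg.Pc_init = {1: 1.0, 2: 1.5, 3: 2.0}[order]
    seg.Pc = seg.Pc_init
    return net, seg


class TestPermeability:
    def test_fully_dilated_immature_reaches_tumour_value(self, remodel):
        _, seg = make_segment(R=remodel.R_max)
        assert update_permeability(seg, remodel) == pytest.approx(remodel.LpT_um)

    def test_mature_keeps_normal_value_whatever_radius(self, remodel):
        _, seg = make_segment(maturity="mature", R=9.5)
        assert update_permeability(seg, remodel) == pytest.approx(remodel.LpN_um)

    def test_monotone_in_radius(self, remodel):
        vals = []
        for r in (4.0, 6.0, 8.0, 10.0):
            _, seg = make_segment(R=r)
            vals.append(update_permeability(seg, remodel))
        assert (np.diff(vals) > 0).all()


class TestCollapsePressure:
    def test_leakiest_wall_hits_floor(self, remodel):
        _, seg = make_segment(R=remodel.R_max, order=3)
        update_permeability(seg, remodel)       # Lp = LpT
        assert update_collapse_pressure(seg, remodel) == pytest.approx(
            0.5 * seg.Pc_init)

    def test_order3_floor_is_one_mmhg(self, remodel):
        _, seg = make_segment(R=remodel.R_max, order=3)
        update_permeability(seg, remodel)
        assert update_collapse_pressure(seg, remodel) == pytest.approx(1.0)

    def test_monotone_decreasing_in_lp(self, remodel):
        pcs = []
        for r in (5.5, 7.0, 8.5, 10.0):
            _, seg = make_segment(R=r, order=2)
            update_permeability(seg, remodel)
            pcs.append(update_collapse_pressure(seg, remodel))
        assert (np.diff(pcs) <= 1e-12).all()

    def test_clamped_to_initial_value(self, remodel):
        _, seg = make_segment(R=1.0, order=2)   # tiny Lp -> law exceeds init
        update_permeability(seg, remodel)
        assert update_collapse_pressure(seg, remodel) == seg.Pc_init


class TestCompliance:
    def test_neutral_bracket_restores_rest_radius(self, remodel):
        """Pv - Pi + Pc = E (6.5 mmHg) leaves R = R0."""
        _, seg = make_segment(R=5.0, R0=6.0)
        crushed = update_radius_compliance(seg, 20.0, 20.0 - 6.5 + seg.Pc,
                                           remodel)
        assert not crushed
        assert seg.R == pytest.approx(6.0)

    def test_mature_segment_pinned_at_rest_radius(self, remodel):
        _, seg = make_segment(maturity="mature", R=5.0, R0=6.0)
        update_radius_compliance(seg, 30.0, 0.0, remodel)
        assert seg.R == 6.0

    def test_monotone_with_exponent_b(self, remodel):
        rs = []
        for pv in (18.0, 20.0, 24.0, 30.0):
            _, seg = make_segment(R=6.0, R0=6.0)
            update_radius_compliance(seg, pv, 16.0, remodel)
            rs.append(seg.R)
        assert (np.diff(rs) > 0).all()
        # b = 0.1: doubling the bracket scales R by 2^0.1
        _, seg = make_segment(R0=6.0)
        update_radius_compliance(seg, 16.0 + 6.5 - seg.Pc, 16.0, remodel)
        r1 = seg.R
        update_radius_compliance(seg, 16.0 + 13.0 - seg.Pc, 16.0, remodel)
        assert seg.R / r1 == pytest.approx(2 ** 0.1)

    def test_non_positive_bracket_is_crush(self, remodel):
        _, seg = make_segment()
        assert update_radius_compliance(seg, 10.0, 30.0, remodel)

    def test_radius_floor_triggers_collapse(self, remodel):
        # R0 0.55 μm and a nearly-crushing bracket: R < R_floor = 0.5 μm
        _, seg = make_segment(R0=0.55)
        crushed = update_radius_compliance(seg, 20.0, 21.3, remodel)
        assert crushed


class TestCoOption:
    def _tumour_fraction_one(self, net):
        return {s.sid: 1.0 for s in net.segments}

    def test_cool_mature_segment_untouched(self, remodel):
        net, seg = make_segment(maturity="mature", R=4.0, R0=4.0)
        cv = np.zeros(net.lattice.n_nodes)
        out = co_opt_and_dilate(net, cv, self._tumour_fraction_one(net),
                                remodel, 1.5)
        assert out == [] and seg.maturity == "mature" and seg.R0 == 4.0

    def test_one_step_dilation_is_0p6_um(self, remodel):
        """0.40 μm/h for a 1.5 h step."""
        net, seg = make_segment(maturity="mature", R=4.0, R0=4.0)
        cv = np.full(net.lattice.n_nodes, remodel.theta_vegf * 10)
        co_opt_and_dilate(net, cv, self._tumour_fraction_one(net), remodel, 1.5)
        assert seg.maturity == "immature"
        assert seg.R0 == pytest.approx(4.6)

    def test_dilation_asymptotes_at_r_max(self, remodel):
        net, seg = make_segment(maturity="mature", R=4.0, R0=4.0)
        cv = np.full(net.lattice.n_nodes, remodel.theta_vegf * 10)
        frac = self._tumour_fraction_one(net)
        for _ in range(30):
            co_opt_and_dilate(net, cv, frac, remodel, 1.5)
        assert seg.R0 == pytest.approx(remodel.R_max)
        assert seg.R <= remodel.R_max

    def test_outside_tumour_not_co_opted(self, remodel):
        net, seg = make_segment(maturity="mature")
        cv = np.full(net.lattice.n_nodes, remodel.theta_vegf * 10)
        co_opt_and_dilate(net, cv, {seg.sid: 0.1}, remodel, 1.5)
        assert seg.maturity == "mature"


class TestCollapse:
    def test_high_wss_resets_counter(self, remodel, rng):
        net, seg = make_segment()
        seg.Q, seg.tau, seg.low_wss_steps = 100.0, 5.0, 7
        collapse_check(net, f0=1.0, tumour_frac={seg.sid: 1.0},
                       params=remodel, rng=rng)
        assert seg.low_wss_steps == 0 and not seg.collapsed

    def test_unsurrounded_vessel_immune(self, remodel, rng):
        net, seg = make_segment()
        seg.Q, seg.tau = 100.0, 0.0
        for _ in range(100):
            collapse_check(net, f0=1.0, tumour_frac={seg.sid: 0.5},
                           params=remodel, rng=rng)
        assert not seg.collapsed

    def test_threshold_is_half_f0(self, remodel, rng):
        net, seg = make_segment()
        seg.Q = 100.0
        seg.tau = 0.51     # f0 = 1.0 -> tau_crit = 0.5
        collapse_check(net, 1.0, {seg.sid: 1.0}, remodel, rng)
        assert seg.low_wss_steps == 0
        seg.tau = 0.49
        collapse_check(net, 1.0, {seg.sid: 1.0}, remodel, rng)
        assert seg.low_wss_steps == 1

    def test_collapse_frequency_matches_linear_law(self, remodel):
        """Empirical collapse frequency at a preset low-WSS duration equals
        min(1, slope*n) within binomial error over 1e4 trials."""
        for n_low in (3, 9, 25):
            hits = 0
            trials = 10000
            rng = np.random.default_rng(100 + n_low)
            for _ in range(trials):
                net, seg = make_segment()
                seg.Q, seg.tau = 100.0, 0.0
                seg.low_wss_steps = n_low - 1
                out = collapse_check(net, 1.0, {seg.sid: 1.0}, remodel, rng)
                hits += len(out)
            p = min(1.0, remodel.collapse_prob_slope * n_low)
            sigma = np.sqrt(max(p * (1 - p), 1e-12) / trials)
            assert abs(hits / trials - p) <= 4 * sigma + 1e-9

    def test_probability_sequence_non_decreasing(self, remodel):
        ps = [min(1.0, remodel.collapse_prob_slope * n) for n in range(1, 40)]
        assert (np.diff(ps) >= 0).all()

    def test_no_resurrection(self, remodel):
        net, seg = make_segment()
        collapse_segment(seg)
        assert seg.collapsed and seg.Q == 0.0
        assert seg not in net.active_segments()


class TestTumourFraction:
    def test_fraction_counts_adjacent_cells(self):
        net = single_segment_network(n=9)
        seg = net.segments[0]
        grid = CellGrid(net.lattice)
        frac0 = segment_tumour_fraction(net, grid)[seg.sid]
        assert frac0 == 0.0
        # put cells right next to half of the path
        path = seg.node_path
        for nd in path[: len(path) // 2]:
            nb = grid.neighbours[nd]
            nb = nb[nb >= 0]
            grid.occupant[nb[0]] = P
        frac = segment_tumour_fraction(net, grid)[seg.sid]
        assert 0.3 <= frac <= 0.7


class TestAngiogenesis:
    def test_uniform_fields_give_symmetric_weights(self, remodel):
        lat = LatticeSpec(9, 9, 9, 10.0)
        grid = CellGrid(lat)
        node = lat.ravel(4, 4, 4)
        cv = np.full(lat.n_nodes, 1e-12)
        cf = np.full(lat.n_nodes, 1.0)
        w = tip_move_weights(node, grid.neighbours[node], cv, cf, remodel, 10.0)
        assert np.allclose(w[1:], w[1])
        assert w[0] > 0

    def test_chemotaxis_limit_steps_up_gradient(self, remodel):
        """phi_h = De = 0 and a linear VEGF ramp: the up-gradient direction
        is the only admissible move."""
        import dataclasses
        params = dataclasses.replace(remodel, De_cm2=0.0, phi_h_cm2=0.0)
        lat = LatticeSpec(9, 9, 9, 10.0)
        grid = CellGrid(lat)
        node = lat.ravel(4, 4, 4)
        cv = np.array([[[i * 1e-12 for _ in range(9)] for _ in range(9)]
                       for i in range(9)], dtype=float).ravel()
        cf = np.zeros(lat.n_nodes)
        w = tip_move_weights(node, grid.neighbours[node], cv, cf, params, 10.0)
        assert w[0] == 0.0
        # +x neighbour (column 1 in the table) carries all the weight
        assert w[2] > 0 and np.isclose(w[1:].sum(), w[2])

    def test_weights_match_stencil_oracle(self, remodel):
        """Mixed-gradient field: weights equal an independent evaluation of
        the discretized motility/chemotaxis/haptotaxis fluxes."""
        lat = LatticeSpec(7, 7, 7, 10.0)
        grid = CellGrid(lat)
        rng = np.random.default_rng(21)
        cv = rng.uniform(0, 2e-12, lat.n_nodes)
        cf = rng.uniform(0, 1, lat.n_nodes)
        node = lat.ravel(3, 3, 3)
        h = 10.0
        w = tip_move_weights(node, grid.neighbours[node], cv, cf, remodel, h)
        chemo = remodel.phi_c_um2 / (1 + remodel.chemo_sat_sigma * cv[node])
        for c, nb in enumerate(grid.neighbours[node]):
            expect = remodel.De_um2 / h ** 2 + (
                chemo * (cv[nb] - cv[node])
                + remodel.phi_h_um2 * (cf[nb] - cf[node])) / (2 * h ** 2)
            assert w[c + 1] == pytest.approx(max(0.0, expect), rel=1e-12)

    def test_sprouts_only_from_immature_hot_segments(self, remodel, rng):
        net = small_tree_network(n=26)
        grid = CellGrid(net.lattice)
        cv = np.zeros(net.lattice.n_nodes)
        tips: list[SproutTip] = []
        import dataclasses
        params = dataclasses.replace(remodel, sprout_prob=1.0)
        ev = angiogenesis_step(tips, net, cv, np.ones_like(cv), grid, params,
                               rng, 10.0)
        assert ev.new_tips == 0            # nothing immature, VEGF cold
        for s in net.segments[:3]:
            s.maturity = "immature"
        cv[:] = params.theta_vegf * 5
        ev = angiogenesis_step(tips, net, cv, np.ones_like(cv), grid, params,
                               rng, 10.0)
        assert ev.new_tips == 3
        assert all(t.parent_sid in {s.sid for s in net.segments[:3]}
                   for t in tips)

    def test_anastomosis_lays_order1_immature_neo_segments(self, remodel):
        """A tip walked into a neighbouring vessel splices junctions and
        produces order-1 immature neo-vessels."""
        rng = np.random.default_rng(3)
        net = small_tree_network(n=26)
        grid = CellGrid(net.lattice)
        lat = net.lattice
        import dataclasses
        params = dataclasses.replace(remodel, sprout_prob=1.0, De_cm2=1e-7)
        for s in net.segments:
            s.maturity = "immature"
        cv = np.full(lat.n_nodes, params.theta_vegf * 5)
        cf = np.ones(lat.n_nodes)
        tips = []
        n_before = len(net.segments)
        made = 0
        for _ in range(60):
            ev = angiogenesis_step(tips, net, cv, cf, grid, params, rng, 10.0)
            made += ev.anastomoses
            if made:
                break
        if made:
            neo = [s for s in net.segments if s.is_neo]
            assert neo
            for s in neo:
                assert s.order == 1 and s.maturity == "immature"
        else:
            pytest.skip("no anastomosis within the step budget (random walk)")
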