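"""Vessel co-option, dilation, wall remodelling, collapse and angiogenesis.

A mature host vessel engulfed by the tumour and exposed to VEGF above the
co-option threshold becomes *immature*: its rest radius grows at the
dilation rate (capped at R_max) and from then on its wall permeability,
collapse pressure and realized radius are dynamic:

    Lp = LpT * (R / R_max)            (immature; mature keeps LpN)
    Pc = Pc_min * (LpT / Lp)          (clamped to [Pc_min, initial Pc])
    R  = R0 * ((Pv - Pi + Pc)/E)^b    (immature; mature keeps R0)

Maturity only moves forward: mature -> immature -> collapsed.  A perfused
vessel surrounded by tumour cells whose wall shear stress stays below
tau_crit = 0.5 f0 (f0 = mean WSS of the order-3 vessels) collapses with a
probability that grows linearly with the time spent below threshold;
compression of the realized radius to the floor collapses it outright.

Angiogenic sprouts start from immature segments where VEGF is high.  Tips
perform a biased random walk over the 6 lattice directions (random
motility, receptor-saturated VEGF chemotaxis, ECM haptotaxis); the trail
is consolidated into order-1 immature neo-segments when the tip
anastomoses with the existing network, which splices new junctions into
both the origin and the target segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import LatticeSpec, RemodellingParams
from .tumour_automaton import EC, EMPTY, M, P, CellGrid
from .vascular_network import (COLLAPSED, IMMATURE, MATURE, VesselNetwork,
                               VesselSegment)


# ---------------------------------------------------------------------------
# Tumour-proximity measure
# ---------------------------------------------------------------------------

def segment_tumour_fraction(net: VesselNetwork, grid: CellGrid
                            ) -> dict[int, float]:
    """Fraction of each active segment's path nodes that have a tumour cell
    within one lattice step (the node itself or a 6-neighbour)."""
    occ = grid.occupant
    tc = (occ >= 1) & (occ <= 4)
    near = tc.copy()
    nb = grid.neighbours
    for c in range(6):
        col = nb[:, c]
        ok = col >= 0
        near[ok] |= tc[col[ok]]
    out: dict[int, float] = {}
    for seg in net.active_segments():
        path = np.asarray(seg.node_path)
        out[seg.sid] = float(near[path].mean())
    return out


# ---------------------------------------------------------------------------
# Co-option, Eq 16-18
# ---------------------------------------------------------------------------

def segment_mean_field(seg: VesselSegment, flat: np.ndarray) -> float:
    return float(flat[np.asarray(seg.node_path)].mean())


def co_opt_and_dilate(net: VesselNetwork, cv_flat: np.ndarray,
                      tumour_frac: dict[int, float], params: RemodellingParams,
                      dt_hours: float) -> list[int]:
    """Mark tumour-engulfed, VEGF-exposed segments immature and dilate
    their rest radius; returns the sids that dilated this step."""
    dil = params.dilation_rate * dt_hours
    out = []
    for seg in net.active_segments():
        inside = tumour_frac.get(seg.sid, 0.0) >= params.co_option_fraction
        hot = segment_mean_field(seg, cv_flat) > params.theta_vegf
        if seg.maturity == MATURE and inside and hot:
            seg.maturity = IMMATURE     # co-option: one-way transition
        if seg.maturity == IMMATURE and hot and seg.R0 < params.R_max:
            seg.R0 = min(params.R_max, seg.R0 + dil)
            seg.R = min(max(seg.R, seg.R0), params.R_max)
            out.append(seg.sid)
    return out


def update_permeability(seg: VesselSegment, params: RemodellingParams) -> float:
    """Wall hydraulic permeability: immature walls leak in proportion to
    their dilation, mature walls keep the normal-tissue value."""
    if seg.maturity == IMMATURE:
        seg.Lp = params.LpT_um * (seg.R / params.R_max)
    else:
        seg.Lp = params.LpN_um
    return seg.Lp


def update_collapse_pressure(seg: VesselSegment, params: RemodellingParams
                             ) -> float:
    """Collapse pressure falls as the wall gets leakier, clamped between
    half the order's initial value (Pc_min) and the initial value."""
    pc_min = 0.5 * seg.Pc_init
    if seg.maturity == IMMATURE and seg.Lp > 0:
        pc = pc_min * (params.LpT_um / seg.Lp)
    else:
        pc = seg.Pc_init
    seg.Pc = float(np.clip(pc, pc_min, seg.Pc_init))
    return seg.Pc


def update_radius_compliance(seg: VesselSegment, pv_local: float,
                             pi_local: float, params: RemodellingParams
                             ) -> bool:
    """Netti wall compliance for immature vessels; returns True when the
    segment is crushed (bracket <= 0 or radius at the floor)."""
    if seg.maturity != IMMATURE:
        seg.R = seg.R0
        return False
    bracket = (pv_local - pi_local + seg.Pc) / params.E
    if bracket <= 0:
        return True
    seg.R = min(seg.R0 * bracket ** params.b, params.R_max)
    if seg.R <= params.R_floor:
        return True
    return False


def collapse_segment(seg: VesselSegment) -> None:
    seg.maturity = COLLAPSED
    seg.Q = seg.Qv = seg.Qt = 0.0
    seg.tau = 0.0


def collapse_check(net: VesselNetwork, f0: float,
                   tumour_frac: dict[int, float], params: RemodellingParams,
                   rng: np.random.Generator, q_eps: float = 1e-9
                   ) -> list[int]:
    """WSS-driven regression of tumour-surrounded vessels.

    A perfused segment whose path is essentially engulfed by tumour cells
    and whose WSS sits below tau_crit = tau_crit_factor * f0 accumulates
    low-WSS steps and collapses with probability
    min(1, collapse_prob_slope * n_low_steps); recovering above threshold
    resets the clock.  Returns collapsed sids.
    """
    tau_crit = params.tau_crit_factor * f0
    out = []
    for seg in net.active_segments():
        surrounded = tumour_frac.get(seg.sid, 0.0) >= params.surrounded_fraction
        circulated = abs(seg.Q) > q_eps
        if surrounded and circulated and seg.tau < tau_crit:
            seg.low_wss_steps += 1
            p = min(1.0, params.collapse_prob_slope * seg.low_wss_steps)
            if rng.random() < p:
                collapse_segment(seg)
                out.append(seg.sid)
        else:
            seg.low_wss_steps = 0
    return out


# ---------------------------------------------------------------------------
# Angiogenesis
# ---------------------------------------------------------------------------

@dataclass
class SproutTip:
    position: int                 # lattice node
    parent_sid: int
    origin_node: int
    trail: list[int] = field(default_factory=list)   # nodes laid so far
    age: int = 0


def _split_segment(net: VesselNetwork, seg: VesselSegment, node: int
                   ) -> int | None:
    """Splice a junction into ``seg`` at ``node``; returns the junction id.

    The two halves inherit every per-segment property.  Splitting at an
    existing endpoint returns that junction unchanged.
    """
    path = seg.node_path
    if node == path[0]:
        return seg.j_from
    if node == path[-1]:
        return seg.j_to
    try:
        at = path.index(node)
    except ValueError:
        return None
    jid = net.add_junction(node)
    tail = path[at:]
    seg.node_path = path[:at + 1]
    old_to = seg.j_to
    seg.j_to = jid
    twin = net.add_segment(jid, old_to, tail, order=seg.order, R=seg.R,
                           R0=seg.R0, Lp=seg.Lp, Pc=seg.Pc, Pc_init=seg.Pc_init,
                           maturity=seg.maturity, H=seg.H, mu=seg.mu,
                           is_neo=seg.is_neo)
    return jid


def tip_move_weights(node: int, neighbours: np.ndarray, cv_flat: np.ndarray,
                     cf_flat: np.ndarray, params: RemodellingParams,
                     h: float) -> np.ndarray:
    """Movement weights over (stay, 6 directions) from the discretized EC
    flux: random motility De, receptor-saturated chemotaxis up the VEGF
    gradient and haptotaxis up the ECM gradient; negative drifts clamp to
    zero (no down-gradient taxis)."""
    w = np.zeros(7)
    w[0] = params.De_um2 / h ** 2
    chemo = params.phi_c_um2 / (1.0 + params.chemo_sat_sigma * cv_flat[node])
    for c in range(6):
        nb = neighbours[c]
        if nb < 0:
            continue
        drift = (chemo * (cv_flat[nb] - cv_flat[node])
                 + params.phi_h_um2 * (cf_flat[nb] - cf_flat[node])) / (2 * h ** 2)
        w[c + 1] = max(0.0, params.De_um2 / h ** 2 + drift)
    return w


@dataclass
class AngioEvents:
    new_tips: int = 0
    moves: int = 0
    anastomoses: int = 0
    terminated: int = 0
    neo_segments: int = 0


def _lay_neo_segments(net: VesselNetwork, j_start: int, trail: list[int],
                      j_end: int, params: RemodellingParams, h: float) -> int:
    """Consolidate a tip trail into order-1 immature neo-segments of about
    ``neo_segment_length`` each, between the spliced junctions."""
    n_nodes = len(trail)
    step_per_seg = max(1, int(round(params.neo_segment_length / h)))
    n_seg = max(1, int(round((n_nodes - 1) / step_per_seg)))
    bounds = [int(round(q * (n_nodes - 1) / n_seg)) for q in range(n_seg + 1)]
    j_up = j_start
    made = 0
    r1 = 4.0   # order-1 initial radius
    for s in range(n_seg):
        sub = trail[bounds[s]:bounds[s + 1] + 1]
        if len(sub) < 2:
            continue
        j_dn = j_end if s == n_seg - 1 else net.add_junction(sub[-1])
        seg = net.add_segment(j_up, j_dn, sub, order=1, R=r1, R0=r1,
                              Lp=params.LpT_um * r1 / params.R_max,
                              Pc=0.5, Pc_init=1.0, maturity=IMMATURE,
                              is_neo=True)
        seg.H = net.inlet_haematocrit
        j_up = j_dn
        made += 1
    return made


def angiogenesis_step(tips: list[SproutTip], net: VesselNetwork,
                      cv: np.ndarray, cf: np.ndarray, grid: CellGrid,
                      params: RemodellingParams, rng: np.random.Generator,
                      h: float) -> AngioEvents:
    """Initiate, move and resolve sprout tips for one macro step.

    Mutates ``tips``, ``net`` and the EC occupancy of ``grid`` in place.
    """
    ev = AngioEvents()
    cv_flat = np.asarray(cv).ravel()
    cf_flat = np.asarray(cf).ravel()
    lat = net.lattice

    # vessel-node ownership for anastomosis tests
    node_owner: dict[int, int] = {}
    for seg in net.active_segments():
        for nd in seg.node_path:
            node_owner[nd] = seg.sid
    sid_map = {s.sid: s for s in net.segments}

    # --- initiation -------------------------------------------------------
    if len(tips) < params.max_tips:
        origins = {(t.parent_sid, t.origin_node) for t in tips}
        for seg in net.active_segments():
            if seg.maturity != IMMATURE or len(tips) >= params.max_tips:
                continue
            if segment_mean_field(seg, cv_flat) <= params.theta_vegf:
                continue
            if rng.random() >= params.sprout_prob:
                continue
            path = seg.node_path
            cand = [nd for nd in path[1:-1]]
            rng.shuffle(cand)
            spacing_steps = int(params.sprout_min_spacing / h)
            for nd in cand:
                at = path.index(nd)
                busy = any(o_s == seg.sid and abs(path.index(o_n) - at)
                           < spacing_steps
                           for o_s, o_n in origins if o_n in path)
                if busy:
                    continue
                tips.append(SproutTip(position=nd, parent_sid=seg.sid,
                                      origin_node=nd, trail=[nd]))
                origins.add((seg.sid, nd))
                ev.new_tips += 1
                break

    # --- movement / anastomosis ------------------------------------------
    survivors: list[SproutTip] = []
    for tip in tips:
        tip.age += 1
        nb = grid.neighbours[tip.position]
        w = tip_move_weights(tip.position, nb, cv_flat, cf_flat, params, h)
        # block re-entering own trail and tumour-occupied nodes
        for c in range(6):
            t = nb[c]
            if t < 0 or t in tip.trail:
                w[c + 1] = 0.0
            elif grid.occupant[t] != EMPTY and t not in node_owner:
                w[c + 1] = 0.0
        tot = w.sum()
        if tot <= 0:
            ev.terminated += 1
            continue
        choice = rng.choice(7, p=w / tot)
        if choice == 0:
            survivors.append(tip)
            continue
        target = int(nb[choice - 1])
        ev.moves += 1
        owner = node_owner.get(target)
        if owner is not None and owner != tip.parent_sid:
            # anastomosis: splice junctions and lay the neo-vessel
            parent = sid_map.get(tip.parent_sid)
            target_seg = sid_map.get(owner)
            if parent is None or parent.collapsed or target_seg.collapsed:
                ev.terminated += 1
                continue
            j_a = _split_segment(net, parent, tip.origin_node)
            j_b = _split_segment(net, target_seg, target)
            if j_a is None or j_b is None:
                ev.terminated += 1
                continue
            trail = tip.trail + [target]
            made = _lay_neo_segments(net, j_a, trail, j_b, params, h)
            ev.neo_segments += made
            ev.anastomoses += 1
            for nd in tip.trail[1:]:
                if grid.occupant[nd] == EMPTY:
                    grid.occupant[nd] = EC
            continue
        tip.position = target
        tip.trail.append(target)
        if grid.occupant[target] == EMPTY:
            grid.occupant[target] = EC
        survivors.append(tip)
    tips[:] = survivors
    return ev
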