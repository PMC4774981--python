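"""Four-phenotype tumour-cell automaton on the simulation lattice.

Phenotypes: proliferating (P), quiescent (Q), necrotic (N) and migrating
(M) glioma cells, plus endothelial cells (EC) laid down by angiogenic
sprouts.  Phenotype switching is driven by the normalized local oxygen
field and the availability of neighbouring space:

* P with oxygen >= theta_prol and a free 6-neighbour divides with
  probability T_age/T_TC (one daughter replaces the parent, ages reset);
  with no free neighbour it goes quiescent.
* any tumour cell with oxygen < theta_surv becomes necrotic; necrotic
  cells older than the clearance delay disappear with probability 0.2
  per step, releasing their node.
* P at intermediate oxygen with space becomes migrating with probability
  0.5 and moves to the free neighbour with the most oxygen; migrating
  cells sitting next to a vessel prefer moves along the vessel axis.
* Q reverts to P when space frees up and oxygen allows; M settles back
  into P when it reaches a proliferation-grade oxygen level.

The sweep is sequential in a freshly randomized order each step, with
immediate effect (a node freed earlier in the sweep can be occupied later
in the same sweep).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ChemConstants, LatticeSpec, PhenotypeParams
from .vascular_network import VesselNetwork

EMPTY, P, Q, N, M, EC = 0, 1, 2, 3, 4, 5
PHENOTYPE_CODE = {"P": P, "Q": Q, "N": N, "M": M}
CODE_NAME = {P: "P", Q: "Q", N: "N", M: "M", EC: "EC"}


class SeedingError(RuntimeError):
    pass


def neighbour_table(lattice: LatticeSpec) -> np.ndarray:
    """(n_nodes, 6) flat indices of the 6-neighbours, -1 outside the domain.

    Column order: -x, +x, -y, +y, -z, +z (axis = column // 2).
    """
    nx, ny, nz = lattice.shape
    idx = np.arange(lattice.n_nodes).reshape(nx, ny, nz)
    out = np.full((lattice.n_nodes, 6), -1, dtype=np.int64)
    pads = []
    for axis in range(3):
        for shift in (1, -1):   # -dir neighbour first (shift +1 brings i-1)
            rolled = np.full_like(idx, -1)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if shift == 1:
                dst[axis] = slice(1, None)
                src[axis] = slice(0, -1)
            else:
                dst[axis] = slice(0, -1)
                src[axis] = slice(1, None)
            rolled[tuple(dst)] = idx[tuple(src)]
            pads.append(rolled.ravel())
    for c in range(6):
        out[:, c] = pads[c]
    return out


@dataclass
class CellGrid:
    """Occupancy, age and necrosis clocks for every lattice node."""

    lattice: LatticeSpec
    occupant: np.ndarray = field(default=None)       # uint8 codes
    age: np.ndarray = field(default=None)            # P-cell age, steps
    necrotic_steps: np.ndarray = field(default=None)
    neighbours: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = self.lattice.n_nodes
        if self.occupant is None:
            self.occupant = np.zeros(n, dtype=np.uint8)
        if self.age is None:
            self.age = np.zeros(n, dtype=np.int32)
        if self.necrotic_steps is None:
            self.necrotic_steps = np.zeros(n, dtype=np.int32)
        if self.neighbours is None:
            self.neighbours = neighbour_table(self.lattice)

    def counts(self) -> dict[str, int]:
        occ = self.occupant
        c = {name: int((occ == code).sum())
             for code, name in CODE_NAME.items()}
        c["total"] = c["P"] + c["Q"] + c["N"] + c["M"]
        return c

    def tumour_nodes(self) -> np.ndarray:
        occ = self.occupant
        return np.flatnonzero((occ >= P) & (occ <= M))

    def free_neighbours(self, node: int) -> np.ndarray:
        nb = self.neighbours[node]
        nb = nb[nb >= 0]
        return nb[self.occupant[nb] == EMPTY]


def vessel_adjacency(net: VesselNetwork, grid: CellGrid
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(adjacent, axis): per-node flags for being on/next to an active
    vessel path, and the local vessel axis (0/1/2, -1 where none).

    Used for the longitudinal migration bias and for the per-segment
    tumour-surround tests.
    """
    n = grid.lattice.n_nodes
    adjacent = np.zeros(n, dtype=bool)
    axis = np.full(n, -1, dtype=np.int8)
    for seg in net.active_segments():
        path = np.asarray(seg.node_path, dtype=np.int64)
        ijk = np.diff([grid.lattice.unravel(int(x)) for x in path], axis=0)
        ax = int(np.argmax(np.abs(ijk).sum(axis=0))) if len(path) > 1 else 0
        adjacent[path] = True
        axis[path] = ax
        nbs = grid.neighbours[path].ravel()
        nbs = nbs[nbs >= 0]
        adjacent[nbs] = True
        axis[nbs] = np.where(axis[nbs] == -1, ax, axis[nbs])
    return adjacent, axis


def seed_initial_cells(grid: CellGrid, net: VesselNetwork, n: int,
                       placement: str, rng: np.random.Generator,
                       phen: PhenotypeParams,
                       explicit_nodes: list[int] | None = None) -> np.ndarray:
    """Place ``n`` proliferating cells adjacent to order-1 capillaries.

    placement 'perfusion_rich' clusters the cells around the order-1 node
    with the densest surrounding vasculature (near the domain centre tie
    break); 'perfusion_poor' around the order-1 node with the sparsest
    vasculature (a blood-supply-deficient corner); 'explicit' uses the
    given nodes.  Ages are uniform on 1..T_TC.  Returns the seeded nodes.
    """
    if n == 0:
        return np.empty(0, dtype=np.int64)
    lat = grid.lattice
    if placement == "explicit":
        if not explicit_nodes or len(explicit_nodes) < n:
            raise SeedingError("explicit placement needs >= n nodes")
        chosen = list(explicit_nodes[:n])
        for node in chosen:
            grid.occupant[node] = P
            grid.age[node] = int(rng.integers(1, phen.T_TC + 1))
        return np.asarray(chosen)

    order1 = [s for s in net.active_segments() if s.order == 1]
    if not order1:
        raise SeedingError("no order-1 capillaries to seed near")
    all_path = net.path_nodes()
    coords = np.array([lat.coords(int(x)) for x in all_path])
    cand_nodes = np.unique(np.concatenate(
        [np.asarray(s.node_path) for s in order1]))
    cand_xyz = np.array([lat.coords(int(x)) for x in cand_nodes])
    # local vasculature density: vessel nodes within 100 μm
    from scipy.spatial import cKDTree
    tree = cKDTree(coords)
    density = np.array([len(tree.query_ball_point(p, 100.0))
                        for p in cand_xyz])
    centre = np.array(lat.extent) / 2.0
    d_centre = np.linalg.norm(cand_xyz - centre, axis=1)
    if placement == "perfusion_rich":
        # central area next to an order-1 capillary, in adequately
        # vascularized surroundings (not the sparse periphery)
        ok = density >= np.median(density)
        pool = np.flatnonzero(ok) if ok.any() else np.arange(len(cand_nodes))
        anchor = cand_nodes[pool[int(np.argmin(d_centre[pool]))]]
    elif placement == "perfusion_poor":
        score = density + d_centre / (d_centre.max() + 1.0)
        anchor = cand_nodes[int(np.argmin(score))]
    else:
        raise SeedingError(f"unknown placement {placement!r}")

    # breadth-first ring growth around the anchor over free nodes
    placed: list[int] = []
    ring = [int(anchor)]
    seen = {int(anchor)}
    while ring and len(placed) < n:
        nxt: list[int] = []
        for node in ring:
            for nb in grid.neighbours[node]:
                if nb < 0 or int(nb) in seen:
                    continue
                seen.add(int(nb))
                nxt.append(int(nb))
                if grid.occupant[nb] == EMPTY and len(placed) < n:
                    placed.append(int(nb))
        ring = nxt
    if len(placed) < n:
        raise SeedingError(f"could not place {n} cells near the anchor")
    for node in placed:
        grid.occupant[node] = P
        grid.age[node] = int(rng.integers(1, phen.T_TC + 1))
    return np.asarray(placed)


def phenotype_sources(grid: CellGrid, chem: ChemConstants,
                      phen: PhenotypeParams
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(mde_src, vegf_src, vegf_sink, o2_sink) per-node rate arrays.

    Rates are the base per-cell constants scaled by the per-phenotype
    multipliers (M cells produce the most MDE/VEGF and burn the most
    oxygen; necrotic debris still signals VEGF but barely consumes).
    Endothelial cells add MDE production and consume VEGF.
    """
    n = grid.lattice.n_nodes
    occ = grid.occupant
    mde = np.zeros(n)
    vegf = np.zeros(n)
    vegf_sink = np.zeros(n)
    o2 = np.zeros(n)
    for name, code in PHENOTYPE_CODE.items():
        mask = occ == code
        if not mask.any():
            continue
        mde[mask] = chem.mu_T * phen.mde_mult[name]
        vegf[mask] = chem.chi * phen.vegf_mult[name]
        o2[mask] = chem.gamma0 * phen.o2_mult[name]
    ec = occ == EC
    mde[ec] += chem.mu_E
    vegf_sink[ec] = chem.eps_ec
    return mde, vegf, vegf_sink, o2


@dataclass
class StepEvents:
    divisions: int = 0
    to_quiescent: int = 0
    from_quiescent: int = 0
    to_necrotic: int = 0
    cleared: int = 0
    to_migrating: int = 0
    migrations: int = 0
    settled: int = 0            # M -> P on reaching rich oxygen


def _pick_move(grid: CellGrid, node: int, free: np.ndarray,
               co_flat: np.ndarray, vessel_adj: np.ndarray,
               vessel_axis: np.ndarray, bias: float,
               rng: np.random.Generator, tol: float = 0.02) -> int:
    """Free neighbour with the highest oxygen; near-ties (within ``tol`` of
    the max) are broken with the longitudinal 2:1 weight when the cell sits
    next to a vessel, else uniformly."""
    co = co_flat[free]
    cands = free[co >= co.max() - tol]
    if len(cands) == 1:
        return int(cands[0])
    w = np.ones(len(cands))
    if vessel_adj[node] and vessel_axis[node] >= 0:
        ax = vessel_axis[node]
        cols = grid.neighbours[node]
        for i, c in enumerate(cands):
            pos = np.flatnonzero(cols == c)[0]
            if pos // 2 == ax:
                w[i] = bias
    w = w / w.sum()
    return int(rng.choice(cands, p=w))


def step_cells(grid: CellGrid, co_norm: np.ndarray, phen: PhenotypeParams,
               rng: np.random.Generator,
               vessel_adj: np.ndarray | None = None,
               vessel_axis: np.ndarray | None = None,
               migration_enabled: bool = True) -> StepEvents:
    """One automaton sweep; mutates ``grid`` in place and returns the
    event tally that fully explains the phenotype-count deltas."""
    co_flat = np.asarray(co_norm).ravel()
    if co_flat.min() < -1e-12 or co_flat.max() > 1.0 + 1e-9:
        raise ValueError("normalized oxygen must lie in [0, 1]")
    if vessel_adj is None:
        vessel_adj = np.zeros(grid.lattice.n_nodes, dtype=bool)
        vessel_axis = np.full(grid.lattice.n_nodes, -1, dtype=np.int8)
    ev = StepEvents()
    occ = grid.occupant
    nodes = grid.tumour_nodes()
    if len(nodes) == 0:
        return ev
    order = nodes[rng.permutation(len(nodes))]
    for node in order:
        state = occ[node]
        if state == EMPTY or state == EC:
            continue
        co = co_flat[node]
        if state == N:
            grid.necrotic_steps[node] += 1
            if (grid.necrotic_steps[node] > phen.clearance_delay
                    and rng.random() < phen.p_necrotic_clear):
                occ[node] = EMPTY
                grid.necrotic_steps[node] = 0
                ev.cleared += 1
            continue
        if co < phen.theta_surv:
            occ[node] = N
            grid.age[node] = 0
            grid.necrotic_steps[node] = 0
            ev.to_necrotic += 1
            continue
        if state == P:
            grid.age[node] = min(grid.age[node] + 1, phen.T_TC)
            free = grid.free_neighbours(node)
            if co >= phen.theta_prol:
                if len(free) == 0:
                    occ[node] = Q
                    ev.to_quiescent += 1
                elif rng.random() < grid.age[node] / phen.T_TC:
                    target = int(free[rng.integers(len(free))])
                    occ[target] = P
                    grid.age[target] = 1
                    grid.age[node] = 1
                    ev.divisions += 1
            else:   # intermediate oxygen
                if len(free) == 0:
                    occ[node] = Q
                    ev.to_quiescent += 1
                elif migration_enabled and rng.random() < phen.p_migrate:
                    target = _pick_move(grid, node, free, co_flat, vessel_adj,
                                        vessel_axis, phen.longitudinal_bias, rng)
                    occ[node] = EMPTY
                    grid.age[node] = 0
                    occ[target] = M
                    ev.to_migrating += 1
                    ev.migrations += 1
        elif state == Q:
            if co >= phen.theta_prol and len(grid.free_neighbours(node)) > 0:
                occ[node] = P
                grid.age[node] = 1
                ev.from_quiescent += 1
        elif state == M:
            if co >= phen.theta_prol:
                occ[node] = P
                grid.age[node] = 1
                ev.settled += 1
                continue
            free = grid.free_neighbours(node)
            if len(free) == 0:
                occ[node] = Q
                ev.to_quiescent += 1
            else:
                target = _pick_move(grid, node, free, co_flat, vessel_adj,
                                    vessel_axis, phen.longitudinal_bias, rng)
                occ[node] = EMPTY
                occ[target] = M
                ev.migrations += 1
    return ev
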