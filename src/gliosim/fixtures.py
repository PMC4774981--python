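"""Small hand-built networks and scalar fields for testing and examples.

Everything here is generated programmatically; fixtures are deliberately
tiny (a handful of segments, <= 15^3 grids) so that brute-force oracles
(dense monolithic solves, direct enumeration) stay trivial.
"""

from __future__ import annotations

import numpy as np

from .config import LatticeSpec, NetworkGenParams
from .vascular_network import (VesselNetwork, assign_initial_state,
                               assign_strahler)


def _straight_path(lattice: LatticeSpec, i0: int, i1: int, j: int, k: int
                   ) -> list[int]:
    step = 1 if i1 >= i0 else -1
    return [lattice.ravel(i, j, k) for i in range(i0, i1 + step, step)]


def single_segment_network(n: int = 11, spacing: float = 10.0,
                           radius: float = 4.0, lp: float = 0.0,
                           h: float = 0.45) -> VesselNetwork:
    """One straight vessel from the inlet face (x = max) to the outlet face."""
    lat = LatticeSpec(n, n, n, spacing)
    net = VesselNetwork(lat, inlet_haematocrit=h)
    mid = n // 2
    path = _straight_path(lat, n - 1, 0, mid, mid)
    ja = net.add_junction(path[0])
    jb = net.add_junction(path[-1])
    seg = net.add_segment(ja, jb, path)
    seg.order, seg.R, seg.R0, seg.Lp, seg.Pc, seg.Pc_init, seg.H = \
        1, radius, radius, lp, 1.0, 1.0, h
    return net


def y_bifurcation_network(n: int = 13, spacing: float = 10.0,
                          lp: float = 0.0, r_parent: float = 6.0,
                          r_daughters: tuple[float, float] = (4.0, 4.0),
                          h: float = 0.45) -> VesselNetwork:
    """Symmetric-geometry Y: parent from the inlet face splits into two
    daughters that run to the outlet face at mirrored lateral positions."""
    lat = LatticeSpec(n, n, n, spacing)
    net = VesselNetwork(lat, inlet_haematocrit=h)
    mid = n // 2
    i_split = n // 2
    parent = _straight_path(lat, n - 1, i_split, mid, mid)
    j_in = net.add_junction(parent[0])
    j_sp = net.add_junction(parent[-1])
    s = net.add_segment(j_in, j_sp, parent)
    s.order, s.R, s.R0, s.Lp, s.Pc, s.Pc_init, s.H = 2, r_parent, r_parent, lp, 1.5, 1.5, h
    for sign, r in zip((+1, -1), r_daughters):
        off = mid + sign * (n // 4)
        lateral = [lat.ravel(i_split, jj, mid)
                   for jj in range(mid, off, sign)]
        down = _straight_path(lat, i_split, 0, off, mid)
        path = lateral + down
        j_end = net.add_junction(path[-1])
        d = net.add_segment(j_sp, j_end, path)
        d.order, d.R, d.R0, d.Lp, d.Pc, d.Pc_init, d.H = 1, r, r, lp, 1.0, 1.0, h
    return net


def asymmetric_network(n: int = 13, spacing: float = 10.0, lp: float = 0.0,
                       h: float = 0.45) -> VesselNetwork:
    """Five-segment asymmetric toy: Y with unequal daughter radii, one
    daughter splitting again.  Used against the monolithic dense oracle."""
    net = y_bifurcation_network(n, spacing, lp=lp, r_parent=6.0,
                                r_daughters=(5.0, 3.0), h=h)
    lat = net.lattice
    mid = n // 2
    # split the thick daughter's end junction into two further branches
    thick = net.segments[1]
    j_sp = thick.j_to
    end_ijk = lat.unravel(net.junction_nodes[j_sp])
    # relocate: cut the thick daughter short at half its descent
    cut = len(thick.node_path) * 2 // 3
    thick.node_path = thick.node_path[:cut]
    new_end = thick.node_path[-1]
    net.junction_nodes[j_sp] = new_end
    i0, j0, k0 = lat.unravel(new_end)
    for sign, r in zip((+1, -1), (3.5, 2.5)):
        lateral = [lat.ravel(i0, j0, kk) for kk in range(k0, k0 + sign * 2, sign)]
        down = _straight_path(lat, i0, 0, j0, k0 + sign * 2)
        path = lateral + down
        j_end = net.add_junction(path[-1])
        d = net.add_segment(j_sp, j_end, path)
        d.order, d.R, d.R0, d.Lp, d.Pc, d.Pc_init, d.H = 1, r, r, lp, 1.0, 1.0, h
    return net


def small_tree_network(n: int = 26, spacing: float = 10.0, seed: int = 0,
                       lpn: float = 3.6e-4) -> VesselNetwork:
    """One generated tree on a reduced lattice with Table-1 initial state."""
    from .vascular_network import generate_network
    gp = NetworkGenParams(n_trees=1, stem_segments=1)
    lat = LatticeSpec(n, n, n, spacing)
    net = generate_network(lat, gp, seed=seed)
    assign_initial_state(net, gp, lpn)
    return net


def minimal_strahler_tree(spacing: float = 10.0) -> VesselNetwork:
    """Depth-1 tree: one parent from the inlet face, two leaves to the
    outlet face; after ordering: parent order 2, leaves order 1."""
    n = 9
    lat = LatticeSpec(n, n, n, spacing)
    net = VesselNetwork(lat)
    mid = n // 2
    parent = _straight_path(lat, n - 1, mid, mid, mid)
    j_in = net.add_junction(parent[0])
    j_sp = net.add_junction(parent[-1])
    net.add_segment(j_in, j_sp, parent)
    for sign in (+1, -1):
        off = mid + sign * 2
        lateral = [lat.ravel(mid, jj, mid) for jj in range(mid, off, sign)]
        down = _straight_path(lat, mid, 0, off, mid)
        path = lateral + down
        j_end = net.add_junction(path[-1])
        net.add_segment(j_sp, j_end, path)
    return net


def gaussian_blob(lattice: LatticeSpec, centre: tuple[float, float, float]
                  | None = None, sigma: float = 60.0, amplitude: float = 1.0
                  ) -> np.ndarray:
    """Smooth toy scalar field with a single interior maximum."""
    nx, ny, nz = lattice.shape
    h = lattice.spacing
    if centre is None:
        centre = ((nx - 1) * h / 2, (ny - 1) * h / 2, (nz - 1) * h / 2)
    x = np.arange(nx) * h
    y = np.arange(ny) * h
    z = np.arange(nz) * h
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    r2 = (X - centre[0]) ** 2 + (Y - centre[1]) ** 2 + (Z - centre[2]) ** 2
    return amplitude * np.exp(-r2 / (2 * sigma ** 2))


def linear_ramp(lattice: LatticeSpec, axis: int = 0, lo: float = 0.0,
                hi: float = 1.0) -> np.ndarray:
    """Linear gradient along one axis."""
    nx, ny, nz = lattice.shape
    ramp = np.linspace(lo, hi, lattice.shape[axis])
    shape = [1, 1, 1]
    shape[axis] = lattice.shape[axis]
    return np.broadcast_to(ramp.reshape(shape), (nx, ny, nz)).copy()
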