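"""Pre-existing vessel network: lattice-embedded Strahler-ordered trees.

The host vasculature is a forest of binary-branching arteriolar trees whose
main stems (Strahler order 3) enter at the x = max face and whose capillary
leaves (order 1) terminate on the x = 0 face, so the imposed 3.5 mmHg
pressure difference perfuses every branch.  Segments are polylines of
lattice edges; a segment occupies every node it traverses, which is what the
oxygen-exchange and cell-vessel-adjacency machinery consume.

Strahler convention: leaves are order 1; a junction of two equal-order
children is one order higher; unequal orders take the maximum; orders are
clamped at 3 (the model's deepest class).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import LatticeSpec, NetworkGenParams

MATURE, IMMATURE, COLLAPSED = "mature", "immature", "collapsed"


class NetworkStructureError(ValueError):
    """Raised for cyclic or otherwise malformed network topology."""


class ConfigurationError(ValueError):
    """Raised when generator parameters cannot fit the lattice."""


@dataclass
class VesselSegment:
    sid: int
    j_from: int                  # upstream junction id
    j_to: int                    # downstream junction id
    node_path: list[int]         # lattice node indices, path[0] at j_from
    order: int = 0               # Strahler order (1..3); neo vessels fixed 1
    R: float = 0.0               # current radius, μm
    R0: float = 0.0              # rest radius, μm (dilation acts on this)
    Lp: float = 0.0              # wall hydraulic permeability, μm/(mmHg s)
    Pc: float = 0.0              # collapse pressure, mmHg
    Pc_init: float = 0.0         # order-assigned initial collapse pressure
    maturity: str = MATURE
    H: float = 0.0               # haematocrit
    Q: float = 0.0               # net segment flow, μm^3/s, signed from->to
    Qv: float = 0.0              # Poiseuille part
    Qt: float = 0.0              # transvascular (Starling) part
    mu: float = 0.0              # apparent viscosity, mmHg s
    tau: float = 0.0             # wall shear stress, mmHg
    low_wss_steps: int = 0
    is_neo: bool = False

    @property
    def n_steps(self) -> int:
        return len(self.node_path) - 1

    def length(self, spacing: float) -> float:
        """Path length Δl in μm (every step is one lattice edge)."""
        return self.n_steps * spacing

    @property
    def collapsed(self) -> bool:
        return self.maturity == COLLAPSED


@dataclass
class VesselNetwork:
    lattice: LatticeSpec
    inlet_haematocrit: float = 0.45
    segments: list[VesselSegment] = field(default_factory=list)
    junction_nodes: dict[int, int] = field(default_factory=dict)  # jid -> lattice node
    junction_pressures: dict[int, float] = field(default_factory=dict)
    _next_jid: int = 0
    _next_sid: int = 0

    # -- construction ------------------------------------------------------
    def add_junction(self, node: int) -> int:
        jid = self._next_jid
        self._next_jid += 1
        self.junction_nodes[jid] = node
        return jid

    def add_segment(self, j_from: int, j_to: int, node_path: list[int],
                    **kwargs) -> VesselSegment:
        if node_path[0] != self.junction_nodes[j_from] or \
           node_path[-1] != self.junction_nodes[j_to]:
            raise NetworkStructureError("segment path must start/end at its junctions")
        seg = VesselSegment(sid=self._next_sid, j_from=j_from, j_to=j_to,
                            node_path=list(node_path), **kwargs)
        self._next_sid += 1
        self.segments.append(seg)
        return seg

    # -- topology helpers --------------------------------------------------
    def boundary_junctions(self) -> tuple[set[int], set[int]]:
        """(inlet, outlet) junction ids: inlets on plane x = max, outlets x = 0."""
        inlets, outlets = set(), set()
        for jid, node in self.junction_nodes.items():
            i, _, _ = self.lattice.unravel(node)
            if i == self.lattice.n_x - 1:
                inlets.add(jid)
            elif i == 0:
                outlets.add(jid)
        return inlets, outlets

    def active_segments(self) -> list[VesselSegment]:
        return [s for s in self.segments if not s.collapsed]

    def adjacency(self, active_only: bool = True) -> dict[int, list[VesselSegment]]:
        adj: dict[int, list[VesselSegment]] = {}
        segs = self.active_segments() if active_only else self.segments
        for s in segs:
            adj.setdefault(s.j_from, []).append(s)
            adj.setdefault(s.j_to, []).append(s)
        return adj

    def path_nodes(self, active_only: bool = True) -> np.ndarray:
        """Unique lattice nodes traversed by (active) segments."""
        segs = self.active_segments() if active_only else self.segments
        if not segs:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate([np.asarray(s.node_path) for s in segs]))


# ---------------------------------------------------------------------------
# Strahler ordering
# ---------------------------------------------------------------------------

def assign_strahler(net: VesselNetwork, max_order: int = 3) -> VesselNetwork:
    """Assign Strahler orders to every segment, rooted at the inlet face.

    Works on forests: a breadth-first orientation from the inlet junctions
    defines parent/child; orders are then computed leaf-up.  Cyclic input
    raises :class:`NetworkStructureError`.  Idempotent.
    """
    inlets, _ = net.boundary_junctions()
    adj = net.adjacency(active_only=False)
    if not net.segments:
        return net
    if not inlets:
        raise NetworkStructureError("network has no inlet junctions on plane x = max")

    # orient: BFS from inlets over junctions
    parent_j: dict[int, int | None] = {j: None for j in inlets}
    children: dict[int, list[VesselSegment]] = {}
    order_of: dict[int, int] = {}
    queue = list(inlets)
    seen_seg: set[int] = set()
    while queue:
        j = queue.pop(0)
        for seg in adj.get(j, []):
            if seg.sid in seen_seg:
                continue
            other = seg.j_to if seg.j_from == j else seg.j_from
            if other in parent_j:
                # reaching an already-visited junction through a new segment
                # closes a cycle
                raise NetworkStructureError(
                    f"cycle detected at junction {other} (segment {seg.sid})")
            seen_seg.add(seg.sid)
            parent_j[other] = j
            children.setdefault(j, []).append(seg)
            queue.append(other)
    if len(seen_seg) != len(net.segments):
        raise NetworkStructureError(
            "network is not a forest rooted at the inlet face "
            f"({len(net.segments) - len(seen_seg)} unreachable segments)")

    # leaf-up order computation; BFS orientation fixes each segment's
    # downstream endpoint
    down_of: dict[int, int] = {}
    for j, segs in children.items():
        for seg in segs:
            down_of[seg.sid] = seg.j_to if seg.j_from == j else seg.j_from

    clamped = False

    def seg_order(seg: VesselSegment, stack: list[int]) -> int:
        nonlocal clamped
        if seg.sid in order_of:
            return order_of[seg.sid]
        kids = children.get(down_of[seg.sid], [])
        if not kids:
            o = 1
        else:
            kid_orders = [seg_order(k, stack) for k in kids]
            top = max(kid_orders)
            o = top + 1 if kid_orders.count(top) >= 2 else top
        if o > max_order:
            clamped = True
            o = max_order
        order_of[seg.sid] = o
        return o

    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10000 + len(net.segments)))
    try:
        for seg in net.segments:
            seg_order(seg, [])
    finally:
        sys.setrecursionlimit(old_limit)
    if clamped:
        warnings.warn(f"tree deeper than Strahler order {max_order}; clamped",
                      stacklevel=2)
    for seg in net.segments:
        seg.order = 1 if seg.is_neo else order_of[seg.sid]
    return net


# ---------------------------------------------------------------------------
# Initial state from the per-order table
# ---------------------------------------------------------------------------

def assign_initial_state(net: VesselNetwork, gen: NetworkGenParams,
                         LpN: float) -> VesselNetwork:
    """Give every ordered segment its initial radius, collapse pressure,
    permeability and maturity.

    R = R0 = diameter/2 per order; Pc per order; all segments start mature
    with the normal-tissue wall permeability.
    """
    for seg in net.segments:
        if seg.order not in gen.diameters:
            raise ConfigurationError(f"segment {seg.sid}: unknown Strahler order "
                                     f"{seg.order}")
        seg.R = seg.R0 = gen.diameters[seg.order] / 2.0
        seg.Pc = seg.Pc_init = gen.collapse_pressures[seg.order]
        seg.maturity = MATURE
        seg.Lp = LpN
        seg.is_neo = False
        seg.H = net.inlet_haematocrit
    return net


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

_LATERALS = [(0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def _walk(lattice: LatticeSpec, start: tuple[int, int, int],
          moves: list[tuple[int, int, int]]) -> list[int]:
    path = [lattice.ravel(*start)]
    pos = list(start)
    for d in moves:
        pos = [pos[0] + d[0], pos[1] + d[1], pos[2] + d[2]]
        if not lattice.in_bounds(*pos):
            raise ConfigurationError("generated path left the lattice")
        path.append(lattice.ravel(*pos))
    return path


def _fit_lateral(lattice: LatticeSpec, pos: tuple[int, int, int], steps: int,
                 rng: np.random.Generator,
                 prefer: tuple[int, int, int] | None = None) -> tuple[int, int, int]:
    """Pick a lateral direction along which `steps` moves stay in bounds."""
    cands = [prefer] if prefer else []
    cands += [_LATERALS[i] for i in rng.permutation(4)]
    for d in cands:
        if d is None:
            continue
        end = (pos[0], pos[1] + d[1] * steps, pos[2] + d[2] * steps)
        if lattice.in_bounds(*end):
            return d
    raise ConfigurationError("no lateral direction fits the lattice; "
                             "domain too small for the requested tree")


def _interleave(down: int, lateral: int, d_lat: tuple[int, int, int],
                rng: np.random.Generator, jitter: float) -> list[tuple[int, int, int]]:
    """Mix `down` -x steps with `lateral` steps into one lattice walk."""
    moves = [(-1, 0, 0)] * down + [d_lat] * lateral
    if jitter > 0 and len(moves) > 1:
        moves = [moves[i] for i in rng.permutation(len(moves))]
    else:
        # deterministic gentle slant: lateral steps spread evenly
        out: list[tuple[int, int, int]] = []
        ratio = lateral / max(1, down + lateral)
        acc = 0.0
        di, dl = 0, 0
        for _ in range(down + lateral):
            acc += ratio
            if acc >= 1.0 and dl < lateral:
                out.append(d_lat)
                dl += 1
                acc -= 1.0
            elif di < down:
                out.append((-1, 0, 0))
                di += 1
            else:
                out.append(d_lat)
                dl += 1
        moves = out
    return moves


def generate_network(lattice: LatticeSpec, gen: NetworkGenParams | None = None,
                     seed: int = 0) -> VesselNetwork:
    """Generate the pre-existing forest of binary arteriolar trees.

    Deterministic for a fixed seed.  Per-order diameters are assigned
    exactly from the generator table; per-order segment lengths equal the
    table values on the default 100^3 lattice and are scaled to the domain
    extent (rounded to lattice steps) on smaller lattices.

    depth semantics via ``gen.stem_segments``: the main stem is a chain of
    order-3 segments; each stem junction carries an order-2 side subtree and
    the stem terminus bifurcates into two order-2 subtrees, each of which
    bifurcates into two order-1 capillary chains that run to the outlet
    face.
    """
    gen = gen or NetworkGenParams()
    h = lattice.spacing
    scale = (lattice.n_x - 1) * h / 990.0 if gen.scale_to_lattice else 1.0
    scale = min(scale, 1.0) if gen.scale_to_lattice else scale
    Ls = {o: max(2, int(round(gen.lengths[o] * scale / h))) for o in (1, 2, 3)}
    L1s, L2s, L3s = Ls[1], Ls[2], Ls[3]

    need = gen.stem_segments * L3s + L2s + L1s
    if lattice.n_x - 1 < need:
        raise ConfigurationError(
            f"lattice too small for one full tree: need x-extent >= "
            f"{need * h:.0f} μm ({need} steps), have {(lattice.n_x - 1) * h:.0f} μm")

    rng = np.random.default_rng(seed)
    net = VesselNetwork(lattice, inlet_haematocrit=0.45)

    # stem root positions on the inlet face, mutually separated
    margin = max(2, lattice.n_y // 6)
    roots: list[tuple[int, int]] = []
    min_sep = max(3, lattice.n_y // (gen.n_trees + 1))
    tries = 0
    while len(roots) < gen.n_trees and tries < 2000:
        tries += 1
        y = int(rng.integers(margin, lattice.n_y - margin))
        z = int(rng.integers(margin, lattice.n_z - margin))
        if all(abs(y - y0) + abs(z - z0) >= min_sep for y0, z0 in roots):
            roots.append((y, z))
    if len(roots) < gen.n_trees:
        raise ConfigurationError("could not place stem roots with the requested "
                                 "separation; reduce n_trees or enlarge the lattice")

    def build_order1_chains(j_parent: int, pos: tuple[int, int, int]) -> None:
        """Two capillary chains from an order-2 terminus down to x = 0."""
        lat_axis = int(rng.integers(0, 2))  # 0 -> y, 1 -> z
        for sign in (+1, -1):
            d_lat = (0, sign, 0) if lat_axis == 0 else (0, 0, sign)
            p = pos
            end = (p[0], p[1] + d_lat[1], p[2] + d_lat[2])
            if not lattice.in_bounds(*end):
                d_lat = (0, -d_lat[1], -d_lat[2])
            total = 1 + pos[0]           # one lateral separation step + descent
            n_seg = max(1, int(round(total / L1s)))
            # near-equal split of the walk into n_seg segments
            bounds = [int(round(q * total / n_seg)) for q in range(n_seg + 1)]
            moves = [d_lat] + [(-1, 0, 0)] * pos[0]
            j_up = j_parent
            walked = 0
            for s in range(n_seg):
                seg_moves = moves[bounds[s]:bounds[s + 1]]
                path = _walk(lattice, p, seg_moves)
                p = lattice.unravel(path[-1])
                j_dn = net.add_junction(path[-1])
                net.add_segment(j_up, j_dn, path)
                j_up = j_dn
                walked += len(seg_moves)

    def build_order2_subtree(j_parent: int, pos: tuple[int, int, int],
                             prefer: tuple[int, int, int] | None) -> None:
        i_j = pos[0]
        # choose down-steps b so the capillary descent (1 + i_j - b) is an
        # exact multiple of L1s, keeping per-order mean lengths on-table
        target = L2s // 2
        cands = [b for b in range(1, L2s) if (1 + i_j - b) % L1s == 0
                 and i_j - b >= L1s - 1]
        b = min(cands, key=lambda x: abs(x - target)) if cands else min(i_j - 1, target)
        b = max(1, b)
        a = L2s - b
        d_lat = _fit_lateral(lattice, pos, a, rng, prefer)
        moves = _interleave(b, a, d_lat, rng, gen.length_jitter)
        path = _walk(lattice, pos, moves)
        j_end = net.add_junction(path[-1])
        net.add_segment(j_parent, j_end, path)
        build_order1_chains(j_end, lattice.unravel(path[-1]))

    for (y, z) in roots:
        pos = (lattice.n_x - 1, y, z)
        j_up = net.add_junction(lattice.ravel(*pos))
        # stem: chain of order-3 segments straight down the x axis
        for s in range(gen.stem_segments):
            path = _walk(lattice, pos, [(-1, 0, 0)] * L3s)
            pos = lattice.unravel(path[-1])
            j_dn = net.add_junction(path[-1])
            net.add_segment(j_up, j_dn, path)
            j_up = j_dn
            if s < gen.stem_segments - 1:
                build_order2_subtree(j_up, pos, None)   # side branch
        # stem terminus: two order-2 subtrees in opposite lateral directions
        axis = int(rng.integers(0, 2))
        d = (0, 1, 0) if axis == 0 else (0, 0, 1)
        build_order2_subtree(j_up, pos, d)
        build_order2_subtree(j_up, pos, (0, -d[1], -d[2]))

    assign_strahler(net)
    return net


# ---------------------------------------------------------------------------
# Plain-text edge-list serialization
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1
_COLUMNS = ("sid j_from j_to order maturity is_neo R R0 Lp Pc Pc_init H Q Qv Qt "
            "mu tau low_wss_steps node_path")


class NetworkParseError(ValueError):
    pass


def write_network(net: VesselNetwork, path: str) -> None:
    """Documented plain-text edge list: header, junction lines, one segment
    per line; lossless for every segment field."""
    with open(path, "w") as fh:
        fh.write(f"# gliosim vessel network v{_FORMAT_VERSION}\n")
        lat = net.lattice
        fh.write(f"# lattice {lat.n_x} {lat.n_y} {lat.n_z} {lat.spacing!r}\n")
        fh.write(f"# inlet_haematocrit {net.inlet_haematocrit!r}\n")
        fh.write(f"# columns: {_COLUMNS}\n")
        for jid in sorted(net.junction_nodes):
            fh.write(f"J {jid} {net.junction_nodes[jid]}\n")
        for s in net.segments:
            fields = [
                str(s.sid), str(s.j_from), str(s.j_to), str(s.order), s.maturity,
                str(int(s.is_neo)), repr(s.R), repr(s.R0), repr(s.Lp), repr(s.Pc),
                repr(s.Pc_init), repr(s.H), repr(s.Q), repr(s.Qv), repr(s.Qt),
                repr(s.mu), repr(s.tau), str(s.low_wss_steps),
                ",".join(map(str, s.node_path)),
            ]
            fh.write("S " + " ".join(fields) + "\n")


def read_network(path: str) -> VesselNetwork:
    lattice = None
    inlet_h = 0.45
    junctions: dict[int, int] = {}
    segments: list[VesselSegment] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                if line.startswith("# lattice"):
                    _, _, nx, ny, nz, sp = line.split()
                    lattice = LatticeSpec(int(nx), int(ny), int(nz), float(sp))
                elif line.startswith("# inlet_haematocrit"):
                    inlet_h = float(line.split()[-1])
                elif line.startswith("#"):
                    continue
                elif line.startswith("J "):
                    _, jid, node = line.split()
                    junctions[int(jid)] = int(node)
                elif line.startswith("S "):
                    parts = line[2:].split()
                    if len(parts) != 19:
                        raise ValueError(f"expected 19 fields, got {len(parts)}")
                    segments.append(VesselSegment(
                        sid=int(parts[0]), j_from=int(parts[1]), j_to=int(parts[2]),
                        node_path=[int(x) for x in parts[18].split(",")],
                        order=int(parts[3]), maturity=parts[4],
                        is_neo=bool(int(parts[5])), R=float(parts[6]),
                        R0=float(parts[7]), Lp=float(parts[8]), Pc=float(parts[9]),
                        Pc_init=float(parts[10]), H=float(parts[11]),
                        Q=float(parts[12]), Qv=float(parts[13]), Qt=float(parts[14]),
                        mu=float(parts[15]), tau=float(parts[16]),
                        low_wss_steps=int(parts[17])))
                else:
                    raise ValueError("unrecognized record")
            except ValueError as e:
                raise NetworkParseError(f"{path}:{ln}: {e}") from e
    if lattice is None:
        raise NetworkParseError(f"{path}: missing '# lattice' header")
    net = VesselNetwork(lattice, inlet_haematocrit=inlet_h,
                        segments=segments, junction_nodes=junctions)
    net._next_jid = max(junctions, default=-1) + 1
    net._next_sid = max((s.sid for s in segments), default=-1) + 1
    return net
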