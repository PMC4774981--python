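"""Coupled intravascular / transvascular / interstitial haemodynamics.

The network problem is Poiseuille flow with Starling leakage: at every
vessel junction the signed segment flows balance; per segment

    Qv = pi R^4 dPv / (8 mu dl)                       (Poiseuille)
    Qt = 2 pi R dl Lp (Pv - Pi - sigma_T (pi_v - pi_i))   (Starling)
    Q  = Qv - Qt

The interstitium obeys Darcy's law Ui = -K grad(Pi) with the transvascular
leakage as a distributed source:

    div(Ui) = Lp (S/V) (Pv - Pi - sigma_T (pi_v - pi_i))

discretized with a 7-point Laplacian, zero normal flow on the domain
boundary, and the source deposited on the lattice nodes each segment
traverses (wall area apportioned per path step).  The two problems are
iterated block Gauss-Seidel style until junction pressures stop moving.

Blood rheology follows the Pries in-vitro relations: apparent viscosity as
a function of tube diameter and haematocrit, and the empirical
phase-separation law for red-cell partition at diverging bifurcations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import FluidConstants, LatticeSpec
from .vascular_network import VesselNetwork, VesselSegment


class FlowError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Rheology (Pries in-vitro relations)
# ---------------------------------------------------------------------------

def relative_viscosity(diameter: float, haematocrit: float) -> float:
    """Relative apparent blood viscosity in a tube (in-vitro law).

    eta_rel(D, H) with D in μm; equals 1 at H = 0 and eta_0.45 at the
    reference haematocrit 0.45.  Continuous and non-decreasing in H.
    """
    D = float(diameter)
    H = float(haematocrit)
    if D <= 0:
        raise ValueError("diameter must be positive")
    if not (0.0 <= H < 1.0):
        raise ValueError("haematocrit must be in [0, 1)")
    eta45 = 220.0 * np.exp(-1.3 * D) + 3.2 - 2.44 * np.exp(-0.06 * D ** 0.645)
    frac = 1.0 / (1.0 + 1.0e-11 * D ** 12)
    C = (0.8 + np.exp(-0.075 * D)) * (-1.0 + frac) + frac
    if H == 0.0:
        return 1.0
    num = (1.0 - H) ** C - 1.0
    den = (1.0 - 0.45) ** C - 1.0
    return 1.0 + (eta45 - 1.0) * num / den


def blood_viscosity(diameter: float, haematocrit: float,
                    plasma_viscosity: float) -> float:
    """Apparent viscosity (mmHg s) = plasma viscosity x eta_rel(D, H)."""
    return plasma_viscosity * relative_viscosity(diameter, haematocrit)


def phase_separation(parent_d: float, d_a: float, d_b: float,
                     parent_h: float, q_a: float, q_b: float,
                     h_max: float = 0.95) -> tuple[float, float]:
    """Haematocrit of two daughter branches at a diverging bifurcation.

    Empirical red-cell partition (Pries): the fraction of parent RBC flux
    entering daughter *a* is a logit-linear function of its fractional
    blood flow, with offset X0 = 0.4/Df and slope/shift depending on the
    daughter diameter ratio and the parent (discharge) haematocrit.
    RBC flux is conserved: Qp Hp = Qa Ha + Qb Hb (before clamping).
    """
    if q_a < 0 or q_b < 0:
        raise ValueError("daughter flows must be non-negative out of the junction")
    q_p = q_a + q_b
    if q_p == 0:
        return 0.0, 0.0
    if q_a == 0.0:
        return 0.0, min(h_max, parent_h * q_p / q_b)
    if q_b == 0.0:
        return min(h_max, parent_h * q_p / q_a), 0.0
    fqb = q_a / q_p
    x0 = 0.4 / parent_d
    if fqb <= x0:
        fqe = 0.0
    elif fqb >= 1.0 - x0:
        fqe = 1.0
    else:
        A = -6.96 * np.log(d_a / d_b) / parent_d
        B = 1.0 + 6.98 * (1.0 - parent_h) / parent_d
        logit_in = np.log((fqb - x0) / (1.0 - fqb - x0))
        fqe = 1.0 / (1.0 + np.exp(-(A + B * logit_in)))
    rbc = q_p * parent_h
    h_a = fqe * rbc / q_a
    h_b = (1.0 - fqe) * rbc / q_b
    clamped = False
    if h_a > h_max:
        clamped, h_a = True, h_max
    if h_b > h_max:
        clamped, h_b = True, h_max
    if clamped:
        import warnings
        warnings.warn("phase separation clamped haematocrit to bounds", stacklevel=2)
    return float(h_a), float(h_b)


# ---------------------------------------------------------------------------
# Elementary per-segment relations
# ---------------------------------------------------------------------------

def poiseuille_conductance(seg: VesselSegment, spacing: float) -> float:
    dl = seg.length(spacing)
    if seg.R <= 0:
        raise FlowError(f"segment {seg.sid}: zero radius on a non-collapsed segment")
    return np.pi * seg.R ** 4 / (8.0 * seg.mu * dl)


def segment_flows(net: VesselNetwork, Pv: dict[int, float],
                  pi_mean: dict[int, float], fluid: FluidConstants) -> None:
    """Fill Qv, Qt and Q = Qv - Qt on every active segment.

    Signs follow the node_path orientation (positive = j_from -> j_to).
    ``pi_mean`` is the interstitial pressure averaged along each path.
    """
    h = net.lattice.spacing
    for seg in net.segments:
        if seg.collapsed:
            seg.Q = seg.Qv = seg.Qt = 0.0
            continue
        dl = seg.length(h)
        g = poiseuille_conductance(seg, h)
        dp = Pv[seg.j_from] - Pv[seg.j_to]
        seg.Qv = g * dp
        pv_bar = 0.5 * (Pv[seg.j_from] + Pv[seg.j_to])
        seg.Qt = 2.0 * np.pi * seg.R * dl * seg.Lp * (
            pv_bar - pi_mean.get(seg.sid, 0.0) - fluid.osmotic_term)
        seg.Q = seg.Qv - seg.Qt


def wall_shear_stress(radius: float, d_pv: float, dl: float) -> float:
    """WSS of a segment: tau = |dPv| R / (2 dl)  (mmHg)."""
    if dl <= 0:
        raise ValueError("segment length must be positive")
    return abs(d_pv) * radius / (2.0 * dl)


def reference_wss_f0(net: VesselNetwork) -> float:
    """Mean WSS over all (uncollapsed) Strahler order-3 segments."""
    taus = [s.tau for s in net.active_segments() if s.order == 3]
    if not taus:
        raise FlowError("no uncollapsed order-3 segments; f0 undefined")
    return float(np.mean(taus))


# ---------------------------------------------------------------------------
# Vessel-node bookkeeping shared with the oxygen solver
# ---------------------------------------------------------------------------

@dataclass
class VesselNodeMap:
    """Per-lattice-node decomposition of the active network.

    For every active segment, every traversed node gets a wall-area share
    (interior path nodes one full step 2 pi R h, endpoints half a step) and
    a linearly interpolated intravascular pressure.
    """

    nodes: np.ndarray          # lattice node index per entry
    seg_ids: np.ndarray        # owning segment sid per entry
    wall_area: np.ndarray      # μm^2 share per entry
    lp: np.ndarray             # wall permeability per entry
    frac: np.ndarray           # position along the path in [0, 1]
    j_from: np.ndarray         # upstream junction id per entry
    j_to: np.ndarray           # downstream junction id per entry
    pv: np.ndarray             # interpolated Pv per entry (set_pressures)

    @classmethod
    def build(cls, net: VesselNetwork, Pv: dict[int, float] | None = None
              ) -> "VesselNodeMap":
        h = net.lattice.spacing
        nodes, sids, areas, lps, fracs, jfs, jts = [], [], [], [], [], [], []
        for seg in net.active_segments():
            path = np.asarray(seg.node_path, dtype=np.int64)
            n = len(path)
            w = np.full(n, h)
            if n > 1:
                w[0] = w[-1] = h / 2.0
            area = 2.0 * np.pi * seg.R * w
            nodes.append(path)
            sids.append(np.full(n, seg.sid))
            areas.append(area)
            lps.append(np.full(n, seg.Lp))
            fracs.append(np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(1))
            jfs.append(np.full(n, seg.j_from))
            jts.append(np.full(n, seg.j_to))
        if not nodes:
            z = np.empty(0)
            zi = np.empty(0, dtype=np.int64)
            out = cls(zi, zi.copy(), z, z.copy(), z.copy(), zi.copy(),
                      zi.copy(), np.empty(0))
        else:
            out = cls(np.concatenate(nodes),
                      np.concatenate(sids).astype(np.int64),
                      np.concatenate(areas), np.concatenate(lps),
                      np.concatenate(fracs),
                      np.concatenate(jfs).astype(np.int64),
                      np.concatenate(jts).astype(np.int64),
                      np.zeros(sum(len(p) for p in nodes)))
        if Pv is not None:
            out.set_pressures(Pv)
        return out

    def set_pressures(self, Pv: dict[int, float]) -> None:
        """Linear interpolation of junction pressures along each path."""
        if len(self.nodes) == 0:
            return
        p0 = np.array([Pv[j] for j in self.j_from])
        p1 = np.array([Pv[j] for j in self.j_to])
        self.pv = (1.0 - self.frac) * p0 + self.frac * p1


# ---------------------------------------------------------------------------
# Sparse 7-point Laplacian with Neumann (zero normal flow) boundaries
# ---------------------------------------------------------------------------

def neumann_laplacian(lattice: LatticeSpec) -> sp.csr_matrix:
    """Graph Laplacian of the lattice (positive semi-definite), 1/h^2 scaled."""
    nx, ny, nz = lattice.shape
    n = lattice.n_nodes
    idx = np.arange(n).reshape(nx, ny, nz)
    rows, cols = [], []
    for axis in range(3):
        a = np.take(idx, np.arange(idx.shape[axis] - 1), axis=axis).ravel()
        b = np.take(idx, np.arange(1, idx.shape[axis]), axis=axis).ravel()
        rows.append(a)
        cols.append(b)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    data = np.ones(len(r))
    A = sp.coo_matrix((data, (r, c)), shape=(n, n))
    A = A + A.T
    lap = sp.diags(np.asarray(A.sum(axis=1)).ravel()) - A
    return (lap / lattice.spacing ** 2).tocsr()


# ---------------------------------------------------------------------------
# Coupled solve
# ---------------------------------------------------------------------------

@dataclass
class FlowSolution:
    Pv: dict[int, float]
    Pi: np.ndarray                      # (nx, ny, nz), mmHg
    residual_rel: float
    iterations: int
    converged: bool
    pi_mean: dict[int, float] = field(default_factory=dict)
    node_map: VesselNodeMap | None = None

    def interstitial_velocity(self, lattice: LatticeSpec, K_um2: float
                              ) -> np.ndarray:
        """Darcy velocity Ui = -K grad(Pi), shape (3, nx, ny, nz), μm/s."""
        grads = np.gradient(self.Pi, lattice.spacing, edge_order=1)
        return -K_um2 * np.stack(grads)


def _solve_network(net: VesselNetwork, fluid: FluidConstants,
                   pi_mean: dict[int, float]) -> dict[int, float]:
    """Linear junction-pressure solve with leakage, Dirichlet at both faces."""
    h = net.lattice.spacing
    segs = net.active_segments()
    if not segs:
        raise FlowError("network has no active segments")
    inlets, outlets = net.boundary_junctions()
    jids = sorted({s.j_from for s in segs} | {s.j_to for s in segs})
    col = {j: i for i, j in enumerate(jids)}
    n = len(jids)
    A = sp.lil_matrix((n, n))
    rhs = np.zeros(n)
    fixed = {}
    for j in jids:
        if j in inlets:
            fixed[j] = fluid.inlet_pressure
        elif j in outlets:
            fixed[j] = fluid.outlet_pressure
    for s in segs:
        g = poiseuille_conductance(s, h)
        dl = s.length(h)
        W = 2.0 * np.pi * s.R * dl * s.Lp
        drive = pi_mean.get(s.sid, 0.0) + fluid.osmotic_term
        for j_this, j_other in ((s.j_from, s.j_to), (s.j_to, s.j_from)):
            r = col[j_this]
            # conservation: sum_out g (P_this - P_other) + W/2 (Pv_bar - drive) = 0
            A[r, col[j_this]] += g + W / 4.0
            A[r, col[j_other]] += -g + W / 4.0
            rhs[r] += W / 2.0 * drive
    # Dirichlet rows
    for j, val in fixed.items():
        r = col[j]
        A.rows[r] = [r]
        A.data[r] = [1.0]
        rhs[r] = val
    x = spla.spsolve(A.tocsr(), rhs)
    return {j: float(x[col[j]]) for j in jids}


def _segment_pi_mean(net: VesselNetwork, pi_flat: np.ndarray) -> dict[int, float]:
    return {s.sid: float(pi_flat[np.asarray(s.node_path)].mean())
            for s in net.active_segments()}


def solve_coupled_flow(net: VesselNetwork, fluid: FluidConstants,
                       lattice: LatticeSpec, pi_init: np.ndarray | None = None,
                       tol: float = 1.0e-6, max_iter: int = 60,
                       under_relax: float = 0.7,
                       lap: sp.csr_matrix | None = None,
                       mg_cache: dict | None = None) -> FlowSolution:
    """Block Gauss-Seidel between the junction-pressure system and the
    interstitial Darcy problem until the max pressure change < tol (mmHg).

    Raises :class:`FlowError` with the residual history on non-convergence.
    """
    n = lattice.n_nodes
    pi_flat = (np.zeros(n) if pi_init is None else np.asarray(pi_init).ravel().copy())
    if lap is None:
        lap = neumann_laplacian(lattice)
    K = fluid.K_um2
    vol = lattice.spacing ** 3
    pv: dict[int, float] = {}
    history: list[float] = []
    x_prev = pi_flat.copy()
    converged = False
    it = 0
    # wall geometry / permeability are fixed for the whole solve: assemble
    # the interstitial operator and its multigrid hierarchy once
    nmap = VesselNodeMap.build(net)
    kappa = np.zeros(n)
    w = nmap.lp * nmap.wall_area / vol                # 1/(mmHg s) per node
    np.add.at(kappa, nmap.nodes, w)
    A = mgp = None
    if kappa.max() > 0.0:
        from .chemical_fields import _reuse_mg
        A = (K * lap + sp.diags(kappa)).tocsr()
        mgp = _reuse_mg(A, kappa, lattice.shape, mg_cache)
    for it in range(1, max_iter + 1):
        pi_mean = _segment_pi_mean(net, pi_flat)
        pv_new = _solve_network(net, fluid, pi_mean)
        dpv = max((abs(pv_new[j] - pv.get(j, pv_new[j])) for j in pv_new),
                  default=0.0)
        pv = pv_new
        nmap.set_pressures(pv)
        if A is None:
            pi_new = pi_flat
        else:
            rhs = np.zeros(n)
            np.add.at(rhs, nmap.nodes, w * (nmap.pv - fluid.osmotic_term))
            # coarse-to-fine: early coupling iterations only need the Pi
            # solve accurate relative to the current fixed-point error
            loose = it > 1 and history and history[-1] > 1e3 * tol
            pi_new, info = spla.cg(A, rhs, x0=x_prev,
                                   rtol=1e-6 if loose else 1e-8, atol=0.0,
                                   maxiter=2000, M=mgp.as_preconditioner())
            if info != 0:
                raise FlowError(f"interstitial CG failed (info={info})")
            x_prev = pi_new
        dpi = float(np.max(np.abs(pi_new - pi_flat))) if it > 1 else np.inf
        pi_flat = under_relax * pi_new + (1.0 - under_relax) * pi_flat
        change = max(dpv if it > 1 else np.inf, dpi)
        history.append(change)
        if it > 1 and change < tol:
            converged = True
            break
    if not converged:
        raise FlowError(f"coupled flow did not converge in {max_iter} iterations; "
                        f"residual history tail {history[-5:]}")

    pi_mean = _segment_pi_mean(net, pi_flat)
    segment_flows(net, pv, pi_mean, fluid)
    h = lattice.spacing
    for s in net.active_segments():
        s.tau = wall_shear_stress(s.R, pv[s.j_from] - pv[s.j_to], s.length(h))
    net.junction_pressures = dict(pv)

    # conservation residual: signed Qv balance minus leakage shares
    adj = net.adjacency()
    inlets, outlets = net.boundary_junctions()
    resid = []
    qscale = np.mean([abs(s.Q) for s in net.active_segments()]) or 1.0
    for j, segs_j in adj.items():
        if j in inlets or j in outlets:
            continue
        bal = 0.0
        for s in segs_j:
            sgn = 1.0 if s.j_to == j else -1.0
            bal += sgn * s.Qv - 0.5 * s.Qt
        resid.append(abs(bal))
    residual_rel = (max(resid) / qscale) if resid else 0.0
    return FlowSolution(Pv=pv, Pi=pi_flat.reshape(lattice.shape),
                        residual_rel=residual_rel, iterations=it,
                        converged=converged, pi_mean=pi_mean, node_map=nmap)


def flow_to_dataframe(net: VesselNetwork, sol: FlowSolution):
    """Per-segment haemodynamic state as a table (id, end pressures, flows,
    velocity, haematocrit, wall shear stress)."""
    import pandas as pd
    rows = []
    for s in net.segments:
        rows.append({
            "sid": s.sid, "order": s.order, "maturity": s.maturity,
            "is_neo": s.is_neo,
            "Pv_from": sol.Pv.get(s.j_from, np.nan),
            "Pv_to": sol.Pv.get(s.j_to, np.nan),
            "Q": s.Q, "Qv": s.Qv, "Qt": s.Qt,
            "Uv": s.Q / (np.pi * s.R ** 2) if s.R > 0 else 0.0,
            "H": s.H, "tau": s.tau, "R": s.R,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Haematocrit propagation
# ---------------------------------------------------------------------------

def propagate_haematocrit(net: VesselNetwork, inlet_h: float | None = None,
                          q_eps: float = 1.0e-9) -> None:
    """Distribute haematocrit from the inlet face through the flow-directed
    network, applying the phase-separation law at diverging bifurcations and
    flux-weighted mixing at converging junctions.

    Junctions are processed in descending pressure order (flow always runs
    down-pressure), which also handles anastomotic loops.  Segments with
    |Q| below ``q_eps`` keep their previous haematocrit.
    """
    if inlet_h is None:
        inlet_h = net.inlet_haematocrit
    pv = net.junction_pressures
    segs = [s for s in net.active_segments() if abs(s.Q) > q_eps]
    if not segs:
        return
    inlets, _ = net.boundary_junctions()
    up_of: dict[int, int] = {}
    out_at: dict[int, list[VesselSegment]] = {}
    in_at: dict[int, list[VesselSegment]] = {}
    for s in segs:
        j_up, j_dn = (s.j_from, s.j_to) if s.Q > 0 else (s.j_to, s.j_from)
        up_of[s.sid] = j_up
        out_at.setdefault(j_up, []).append(s)
        in_at.setdefault(j_dn, []).append(s)
    order = sorted(out_at, key=lambda j: -pv.get(j, np.inf))
    for j in order:
        outs = out_at[j]
        ins = in_at.get(j, [])
        if j in inlets or not ins:
            rbc = sum(abs(s.Q) for s in outs) * inlet_h
            parent_d = max((2.0 * s.R for s in outs))
            parent_h = inlet_h
        else:
            rbc = sum(abs(s.Q) * s.H for s in ins)
            q_in = sum(abs(s.Q) for s in ins)
            parent_h = rbc / q_in if q_in > 0 else 0.0
            parent_d = 2.0 * max(ins, key=lambda s: abs(s.Q)).R
        q_out = sum(abs(s.Q) for s in outs)
        if q_out <= 0:
            continue
        if len(outs) == 2:
            h_a, h_b = phase_separation(parent_d, 2 * outs[0].R, 2 * outs[1].R,
                                        rbc / q_out, abs(outs[0].Q), abs(outs[1].Q))
            outs[0].H, outs[1].H = h_a, h_b
        else:
            h_mix = min(0.95, rbc / q_out)
            for s in outs:
                s.H = h_mix
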