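"""Quasi-steady chemical fields: ECM, MDE, VEGF and three-domain oxygen.

ECM is degraded by matrix-degradation enzymes (MDE); MDE diffuses, is
produced by tumour and endothelial cells and decays; VEGF diffuses, is
produced by tumour cells and the ECM, consumed by endothelial cells and
decays.  Oxygen is computed in three coupled domains: advection of free and
haemoglobin-bound oxygen inside the vessels, Fick flux across the vessel
wall, and diffusion with cellular consumption in the tissue.

Because the chemicals relax much faster than cells move, the engine drives
every field to steady state within each 1.5 h macro step.  The transient
explicit steppers (inner step 5 s, automatic CFL sub-stepping) are part of
the public surface and are used for the small-step tests; the engine's
steady states are obtained from the equivalent sparse linear systems, and
for intravascular oxygen from an exact downstream march of the upwind
discretization (the steady solution of the advection equations).

Working units: μm, s; MDE/VEGF in molar; oxygen normalized so the inlet
free concentration is 1.  The normalized-to-running-max oxygen field that
phenotype decisions consume is produced by :func:`normalize_oxygen` only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import ChemConstants, LatticeSpec
from .mg import LatticeMultigrid
from .vascular_network import VesselNetwork

logger = logging.getLogger(__name__)


class SteadyStateError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Discrete operators
# ---------------------------------------------------------------------------

def laplacian_apply(f: np.ndarray, h: float) -> np.ndarray:
    """7-point Laplacian with zero-flux (mirror) boundaries, 1/h^2 scaled."""
    g = np.pad(f, 1, mode="edge")
    out = (g[2:, 1:-1, 1:-1] + g[:-2, 1:-1, 1:-1]
           + g[1:-1, 2:, 1:-1] + g[1:-1, :-2, 1:-1]
           + g[1:-1, 1:-1, 2:] + g[1:-1, 1:-1, :-2]
           - 6.0 * f)
    return out / h ** 2


def _substeps(dt: float, D: float, h: float) -> tuple[int, float]:
    if D <= 0:
        return 1, dt
    dt_stable = h ** 2 / (6.0 * D)
    n = max(1, int(np.ceil(dt / (0.9 * dt_stable))))
    if n > 1:
        logger.debug("CFL sub-stepping: %d sub-steps of %.3g s", n, dt / n)
    return n, dt / n


# ---------------------------------------------------------------------------
# ECM / MDE / VEGF
# ---------------------------------------------------------------------------

def update_ecm(cf: np.ndarray, cm: np.ndarray, dt: float, delta: float
               ) -> np.ndarray:
    """ECM degradation dCf/dt = -delta Cm Cf, integrated exactly per node."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return cf * np.exp(-delta * cm * dt)


def update_mde(cm: np.ndarray, source: np.ndarray, dt: float,
               chem: ChemConstants, h: float) -> np.ndarray:
    """One explicit transient step of the MDE equation.

    dCm/dt = Dm lap(Cm) + source - lambda Cm, with automatic sub-stepping
    when dt violates the diffusive stability limit.
    """
    n, dts = _substeps(dt, chem.Dm_um2, h)
    out = cm
    for _ in range(n):
        out = out + dts * (chem.Dm_um2 * laplacian_apply(out, h)
                           + source - chem.lambda_mde * out)
    return np.maximum(out, 0.0)


def update_vegf(cv: np.ndarray, source: np.ndarray, sink: np.ndarray,
                dt: float, chem: ChemConstants, h: float) -> np.ndarray:
    """One explicit transient VEGF step; clamped at zero where endothelial
    consumption would drive the concentration negative."""
    n, dts = _substeps(dt, chem.Dv_um2, h)
    out = cv
    for _ in range(n):
        out = out + dts * (chem.Dv_um2 * laplacian_apply(out, h)
                           + source - sink - chem.theta_vegf_decay * out)
        out = np.maximum(out, 0.0)
    return out


def steady_reaction_diffusion(D: float, decay: float, source: np.ndarray,
                              lattice: LatticeSpec, lap: sp.csr_matrix,
                              x0: np.ndarray | None = None,
                              rtol: float = 1.0e-10,
                              cache: dict | None = None) -> np.ndarray:
    """Steady state of dC/dt = D lap C - decay C + source (source >= 0 net
    production per node, may contain negative sink entries; result clipped
    at zero).

    Solves (D*lap_matrix + decay I) C = source with multigrid-
    preconditioned conjugate gradients; ``lap`` is the positive-
    semidefinite Neumann Laplacian.  Pass a ``cache`` dict to reuse the
    assembled operator and its multigrid hierarchy across calls with the
    same (D, decay).
    """
    shape = lattice.shape
    b = np.asarray(source, dtype=float).ravel()
    if decay <= 0 and b.min() >= 0 and b.max() > 0:
        raise SteadyStateError("no decay and net production: no steady state")
    key = (float(D), float(decay))
    if cache is not None and key in cache:
        A, mg = cache[key]
    else:
        A = (D * lap + decay * sp.identity(lattice.n_nodes, format="csr")).tocsr()
        mg = LatticeMultigrid(A, shape)
        if cache is not None:
            cache[key] = (A, mg)
    x0v = None if x0 is None else np.asarray(x0).ravel()
    x, info = spla.cg(A, b, x0=x0v, rtol=rtol, atol=0.0, maxiter=2000,
                      M=mg.as_preconditioner())
    if info != 0:
        raise SteadyStateError(f"steady-state CG failed (info={info})")
    return np.maximum(x.reshape(shape), 0.0)


# ---------------------------------------------------------------------------
# Haemoglobin equilibrium
# ---------------------------------------------------------------------------

def so2(co_f: np.ndarray | float, chem: ChemConstants) -> np.ndarray | float:
    """Haemoglobin oxygen saturation, Hill form: monotone, SO2(0) = 0,
    SO2 -> 1 as the free concentration grows, 0.5 at the half-saturation."""
    c = np.maximum(np.asarray(co_f, dtype=float), 0.0)
    n = chem.hill_n
    s = c ** n / (c ** n + chem.o2_half_sat ** n)
    return float(s) if np.isscalar(co_f) else s


def total_blood_o2(co_f: np.ndarray | float, h: float, chem: ChemConstants):
    """Total (free + bound) blood oxygen at equilibrium:
    T = C_F + hb_capacity * H * SO2(C_F)   (Co_B = 4 H C_Hb SO2)."""
    return co_f + chem.hb_capacity * h * so2(co_f, chem)


def _free_from_total(h: float, chem: ChemConstants, c_max: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Monotone lookup (T_grid, C_grid) used to seed the Newton inversion."""
    c = np.linspace(0.0, max(c_max, chem.inlet_o2) * 1.5, 256)
    t = np.asarray(total_blood_o2(c, h, chem))
    return t, c


def free_from_total(t: np.ndarray | float, h: float, chem: ChemConstants
                    ) -> np.ndarray | float:
    """Invert T = C + capacity*H*SO2(C) for the free concentration C.

    T(C) is smooth and strictly increasing; a coarse lookup provides the
    initial guess and a few safeguarded Newton steps polish it to machine
    precision.
    """
    scalar = np.isscalar(t)
    tv = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(tv)
    pos = tv > 0
    if pos.any():
        tg, cg = _free_from_total(h, chem, float(tv.max()))
        tp = tv[pos]
        c = np.minimum(np.interp(tp, tg, cg), tp)
        lo = np.zeros_like(c)
        hi = tp.copy()                      # T(c) >= c, so the root <= t
        n, k, cap = chem.hill_n, chem.o2_half_sat, chem.hb_capacity * h
        for _ in range(60):
            cn = np.maximum(c, 1e-300) ** n
            s = cn / (cn + k ** n)
            f = c + cap * s - tp
            if np.max(np.abs(f)) < 1e-13 * max(1.0, float(tv.max())):
                break
            lo = np.where(f < 0, c, lo)
            hi = np.where(f > 0, c, hi)
            ds = n * s * (1.0 - s) / np.maximum(c, 1e-300)
            c_new = c - f / (1.0 + cap * ds)
            bad = (c_new <= lo) | (c_new >= hi)
            c = np.where(bad, 0.5 * (lo + hi), c_new)
        out[pos] = np.maximum(c, 0.0)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Trans-wall flux
# ---------------------------------------------------------------------------

def wall_mass_transfer(lp: float, lpn: float, chem: ChemConstants) -> float:
    """Free-O2 wall mass-transfer coefficient, μm/s.

    The Fick flux J = -Lp (Co_Fex - Co_Fin) / (alpha w) is carried as
    J = k (Co_Fin - Co_Fex); k is the normal-wall coefficient scaled by the
    segment's hydraulic permeability ratio Lp/LpN, so leaky immature walls
    exchange proportionally faster.
    """
    return chem.wall_o2_perm * (lp / lpn)


def transwall_oxygen_flux(lp: float, lpn: float, co_fin: float, co_fex: float,
                          area: float, volume: float, chem: ChemConstants
                          ) -> tuple[float, float]:
    """(J, tissue rate): J in conc·μm/s per unit wall area, positive into
    the tissue; the tissue node gains J*A/V (Fick's law over the wall)."""
    k = wall_mass_transfer(lp, lpn, chem)
    J = k * (co_fin - co_fex)
    return J, J * area / volume


# ---------------------------------------------------------------------------
# Intravascular transport
# ---------------------------------------------------------------------------

@dataclass
class IntravascularOxygen:
    """Per-segment free oxygen along the node path (bound follows the
    haemoglobin equilibrium)."""
    co_fin: dict[int, np.ndarray] = field(default_factory=dict)

    def co_b(self, net: VesselNetwork, chem: ChemConstants) -> dict[int, np.ndarray]:
        out = {}
        for s in net.segments:
            if s.sid in self.co_fin:
                out[s.sid] = chem.hb_capacity * s.H * np.asarray(
                    so2(self.co_fin[s.sid], chem))
        return out


def advect_intravascular_oxygen(net: VesselNetwork, oxy: IntravascularOxygen,
                                dt: float, chem: ChemConstants,
                                inlet_value: float | None = None
                                ) -> IntravascularOxygen:
    """One explicit first-order upwind step of free+bound transport along
    each segment in its flow direction, with flux-weighted junction mixing
    and the haemoglobin equilibrium re-imposed afterwards.

    Transient counterpart of the steady march used by the engine; intended
    for small fixtures (sub-steps if u dt > h).
    """
    if inlet_value is None:
        inlet_value = chem.inlet_o2
    h = net.lattice.spacing
    inlets, _ = net.boundary_junctions()
    segs = [s for s in net.active_segments()]
    new = IntravascularOxygen({sid: arr.copy() for sid, arr in oxy.co_fin.items()})
    # junction totals for mixing (flux-weighted over inflowing segment ends)
    for s in segs:
        if s.sid not in new.co_fin:
            new.co_fin[s.sid] = np.zeros(len(s.node_path))
    max_u = max((abs(s.Q) / (np.pi * s.R ** 2) for s in segs), default=0.0)
    n_sub = max(1, int(np.ceil(max_u * dt / h)))
    dts = dt / n_sub
    for _ in range(n_sub):
        # junction mixing: O2 flux conserved, free concentration continuous;
        # each outgoing branch re-loads haemoglobin at its own haematocrit
        mix_flux: dict[int, float] = {}
        mix_o2: dict[int, float] = {}
        mix_rbc: dict[int, float] = {}
        for s in segs:
            if abs(s.Q) <= 0:
                continue
            c = new.co_fin[s.sid]
            exit_c = c[-1] if s.Q > 0 else c[0]
            j_dn = s.j_to if s.Q > 0 else s.j_from
            t_exit = float(total_blood_o2(exit_c, s.H, chem))
            mix_flux[j_dn] = mix_flux.get(j_dn, 0.0) + abs(s.Q)
            mix_o2[j_dn] = mix_o2.get(j_dn, 0.0) + abs(s.Q) * t_exit
            mix_rbc[j_dn] = mix_rbc.get(j_dn, 0.0) + abs(s.Q) * s.H
        c_mix: dict[int, float] = {}
        for j, q in mix_flux.items():
            if q > 0:
                c_mix[j] = float(free_from_total(mix_o2[j] / q,
                                                 mix_rbc[j] / q, chem))
        for s in segs:
            c = new.co_fin[s.sid]
            if abs(s.Q) <= 0 or len(c) < 2:
                continue
            u = abs(s.Q) / (np.pi * s.R ** 2)
            t = np.asarray(total_blood_o2(c, s.H, chem), dtype=float)
            j_up = s.j_from if s.Q > 0 else s.j_to
            if j_up in inlets:
                t_up = float(total_blood_o2(inlet_value, s.H, chem))
            elif j_up in c_mix:
                t_up = float(total_blood_o2(c_mix[j_up], s.H, chem))
            else:
                t_up = t[0] if s.Q > 0 else t[-1]
            if s.Q > 0:
                upstream = np.concatenate(([t_up], t[:-1]))
            else:
                upstream = np.concatenate((t[1:], [t_up]))
            t_new = t + u * dts / h * (upstream - t)
            new.co_fin[s.sid] = np.asarray(free_from_total(t_new, s.H, chem))
    return new


# ---------------------------------------------------------------------------
# Steady three-domain oxygen
# ---------------------------------------------------------------------------

@dataclass
class OxygenResult:
    tissue: np.ndarray                 # raw free tissue O2, lattice shape
    normalized: np.ndarray             # tissue / running max, in [0, 1]
    intravascular: IntravascularOxygen
    supply_by_order: dict[int, float]  # deposited O2 flux per Strahler order
    outer_iterations: int = 0


def normalize_oxygen(co: np.ndarray) -> np.ndarray:
    """Divide by the current global maximum (all-zero field stays zero)."""
    m = float(co.max())
    return co / m if m > 0 else np.zeros_like(co)


def _newton_free(t: float, cap: float, n_h: float, k_h: float,
                 c0: float) -> float:
    """Invert T(c) = c + cap*SO2(c) for c; T is strictly increasing.

    Bisection-safeguarded Newton: the steep part of the Hill curve can make
    a bare Newton step cycle, so iterates are kept inside the shrinking
    bracket [lo, hi] (root <= t since T(c) >= c)."""
    if t <= 0:
        return 0.0
    lo, hi = 0.0, t
    c = min(max(c0, 1e-9), t)
    for _ in range(100):
        cb = max(c, 1e-300)
        sat = cb ** n_h / (cb ** n_h + k_h ** n_h)
        f = c + cap * sat - t
        if abs(f) < 1e-12 * max(1.0, t):
            break
        if f > 0:
            hi = c
        else:
            lo = c
        ds = n_h * sat * (1.0 - sat) / cb
        c_new = c - f / (1.0 + cap * ds)
        if not (lo < c_new < hi):
            c_new = 0.5 * (lo + hi)
        c = c_new
    return max(c, 0.0)


def _march_intravascular(net: VesselNetwork, tissue_flat: np.ndarray,
                         chem: ChemConstants, lpn: float, q_eps: float = 1e-9):
    """Exact steady downstream march of the upwind intravascular transport.

    Returns per-vessel-node arrays (lattice node, conductance g, blood free
    conc entering the node, deposition flux, segment order) plus the
    per-segment free-concentration profiles.
    """
    h = net.lattice.spacing
    pv = net.junction_pressures
    inlets, _ = net.boundary_junctions()
    segs = [s for s in net.active_segments() if abs(s.Q) > q_eps]
    oxy = IntravascularOxygen()
    rows_node, rows_g, rows_cb, rows_dep, rows_ord = [], [], [], [], []
    if not segs:
        return oxy, (np.empty(0, np.int64), np.empty(0), np.empty(0),
                     np.empty(0), np.empty(0, np.int64))
    out_at: dict[int, list] = {}
    in_at: dict[int, list] = {}
    for s in segs:
        j_up = s.j_from if s.Q > 0 else s.j_to
        j_dn = s.j_to if s.Q > 0 else s.j_from
        out_at.setdefault(j_up, []).append(s)
        in_at.setdefault(j_dn, []).append(s)
    cf_exit: dict[int, float] = {}
    order_j = sorted(set(out_at) | set(in_at), key=lambda j: -pv.get(j, np.inf))
    for j in order_j:
        ins = in_at.get(j, [])
        if j in inlets or not ins:
            c_junction = None    # boundary: inlet concentration
        else:
            # O2 flux is conserved through the junction and the free
            # concentration is continuous; each branch's bound load follows
            # its own haematocrit.  Strong leakage can drive a segment
            # against the pressure ordering: mix only inflows already
            # marched, fall back to equilibrium with the local tissue.
            known = [s for s in ins if s.sid in cf_exit]
            q_in = sum(abs(s.Q) for s in known)
            if q_in > 0:
                phi = sum(abs(s.Q) * total_blood_o2(cf_exit[s.sid], s.H, chem)
                          for s in known)
                h_mix = sum(abs(s.Q) * s.H for s in known) / q_in
                c_junction = _newton_free(
                    phi / q_in, chem.hb_capacity * h_mix, chem.hill_n,
                    chem.o2_half_sat, max(cf_exit[s.sid] for s in known))
            else:
                c_junction = float(tissue_flat[net.junction_nodes[j]])
        for s in out_at.get(j, []):
            q = abs(s.Q)
            c0 = chem.inlet_o2 if c_junction is None else c_junction
            t = float(total_blood_o2(c0, s.H, chem))
            path = np.asarray(s.node_path, dtype=np.int64)
            if s.Q < 0:
                path = path[::-1]
            n = len(path)
            w = np.full(n, h)
            w[0] = w[-1] = h / 2.0
            area = 2.0 * np.pi * s.R * w
            k = wall_mass_transfer(s.Lp, lpn, chem)
            g = q * (1.0 - np.exp(-k * area / q))
            cf = np.empty(n)
            dep = np.empty(n)
            # scalar Newton inversion of T(c), seeded by the previous node
            n_h, k_h, cap = chem.hill_n, chem.o2_half_sat, chem.hb_capacity * s.H
            c_free = min(t, chem.inlet_o2)   # Newton refines from here
            for m in range(n):
                c_free = _newton_free(t, cap, n_h, k_h, c_free)
                cf[m] = c_free
                d = g[m] * (c_free - tissue_flat[path[m]])
                # cannot extract below local equilibrium with the tissue
                d = min(d, q * max(0.0, c_free - tissue_flat[path[m]])) \
                    if d > 0 else d
                dep[m] = d
                t = t - d / q
            cf_exit[s.sid] = _newton_free(t, cap, n_h, k_h, c_free)
            prof = cf if s.Q > 0 else cf[::-1]
            oxy.co_fin[s.sid] = prof
            rows_node.append(path)
            rows_g.append(g)
            rows_cb.append(cf)
            rows_dep.append(dep)
            rows_ord.append(np.full(n, s.order, dtype=np.int64))
    # segments never reached (e.g. blind loops) carry no oxygen
    return oxy, (np.concatenate(rows_node), np.concatenate(rows_g),
                 np.concatenate(rows_cb), np.concatenate(rows_dep),
                 np.concatenate(rows_ord))


def _tissue_steady(A: sp.csr_matrix, mg: LatticeMultigrid,
                   cb_source: np.ndarray, sink: np.ndarray,
                   x0: np.ndarray | None, c_crit: float,
                   rtol: float = 1.0e-5, max_sink_iter: int = 8
                   ) -> np.ndarray:
    """Steady tissue diffusion with Robin vessel coupling and cellular
    consumption.

    Consumption per cell is zero-order (rate ``sink``) above the cut-in
    concentration ``c_crit`` and falls off linearly below it, so supply-
    limited regions relax smoothly to ~0 instead of toggling a hard active
    set.  The (small) nonlinearity is resolved by a fixed-point iteration
    on the hypoxic node set; the linear-regime sink enters the diagonal.
    """
    n = A.shape[0]
    M = mg.as_preconditioner()
    x = np.zeros(n) if x0 is None else np.asarray(x0).ravel().copy()
    has_sink = sink > 0
    hypoxic = has_sink & (x < c_crit)
    for _ in range(max_sink_iter):
        extra = np.where(hypoxic, sink / c_crit, 0.0)
        A_it = A + sp.diags(extra) if hypoxic.any() else A
        b = cb_source - sink * (~hypoxic & has_sink)
        x, info = spla.cg(A_it, b, x0=x, rtol=rtol, atol=0.0, maxiter=2000,
                          M=M)
        if info != 0:
            raise SteadyStateError(f"tissue O2 CG failed (info={info})")
        new_hyp = has_sink & (x < c_crit)
        if (new_hyp == hypoxic).all():
            break
        hypoxic = new_hyp
    return np.maximum(x, 0.0)


def _reuse_mg(A: sp.csr_matrix, kappa: np.ndarray, shape, cache: dict | None,
              drift: float = 0.1) -> LatticeMultigrid:
    """Rebuild the multigrid hierarchy only when the Robin diagonal has
    drifted; a stale hierarchy is still a valid CG preconditioner."""
    if cache is not None and "mg" in cache:
        k0 = cache["kappa"]
        denom = float(np.abs(k0).sum()) + 1e-300
        if float(np.abs(kappa - k0).sum()) / denom < drift:
            return cache["mg"]
    mg = LatticeMultigrid(A, shape)
    if cache is not None:
        cache["mg"] = mg
        cache["kappa"] = kappa.copy()
    return mg


def oxygen_to_steady(net: VesselNetwork, o2_sink: np.ndarray,
                     chem: ChemConstants, lattice: LatticeSpec,
                     lap: sp.csr_matrix, lpn: float,
                     co_init: np.ndarray | None = None,
                     max_outer: int = 80, under_relax: float = 1.0,
                     mg_cache: dict | None = None) -> OxygenResult:
    """Iterate intravascular march -> trans-wall exchange -> tissue
    diffusion to the coupled steady state.

    ``o2_sink`` is the per-node zero-order consumption rate (conc/s,
    phenotype-scaled).  Convergence: max relative tissue change below
    ``chem.steady_tol``.  Returns the raw and normalized tissue fields, the
    intravascular profiles and the oxygen supply attributed to each
    Strahler order.
    """
    vol = lattice.spacing ** 3
    n = lattice.n_nodes
    tissue = (np.zeros(n) if co_init is None
              else np.asarray(co_init, dtype=float).ravel().copy())
    sink = np.asarray(o2_sink, dtype=float).ravel()
    Do = chem.Do_um2
    oxy = IntravascularOxygen()
    supply: dict[int, float] = {}
    # exchange conductances depend only on the (fixed) flow solution, so the
    # tissue operator and its multigrid hierarchy are built once per call
    oxy, (nodes, g, cb, dep, ords) = _march_intravascular(net, tissue, chem, lpn)
    if len(nodes) == 0:
        co = np.zeros(lattice.shape)
        return OxygenResult(co, np.zeros(lattice.shape), oxy, {}, 0)
    kappa = np.zeros(n)
    np.add.at(kappa, nodes, g / vol)
    A = (Do * lap + sp.diags(kappa)).tocsr()
    mg = _reuse_mg(A, kappa, lattice.shape, mg_cache)
    it = 0
    ur = under_relax
    prev_change = np.inf
    delta_prev: np.ndarray | None = None
    for it in range(1, max_outer + 1):
        oxy, (nodes, g, cb, dep, ords) = _march_intravascular(
            net, tissue, chem, lpn)
        rhs = np.zeros(n)
        np.add.at(rhs, nodes, g * cb / vol)
        new = _tissue_steady(A, mg, rhs, sink, tissue, chem.o2_linear_crit)
        scale = max(float(new.max()), 1e-30)
        delta = new - tissue
        change = float(np.max(np.abs(delta))) / scale
        if change < chem.steady_tol:
            tissue = new
            break
        # damp only if the fixed point oscillates; recover afterwards
        if change > prev_change:
            ur = max(0.3, ur * 0.7)
            delta_prev = None
        else:
            ur = min(under_relax, ur * 1.15)
        prev_change = change
        tissue = ur * new + (1.0 - ur) * tissue
        # Aitken extrapolation along the dominant contraction mode: with a
        # smooth linear rate rho, the remaining error is delta*rho/(1-rho)
        if delta_prev is not None and ur == under_relax:
            num = float(delta @ delta_prev)
            den = float(delta_prev @ delta_prev)
            rho = num / den if den > 0 else 0.0
            if 0.05 < rho < 0.9:
                tissue = np.maximum(tissue + delta * (rho / (1.0 - rho)), 0.0)
                delta_prev = None
            else:
                delta_prev = delta
        else:
            delta_prev = delta
    else:
        raise SteadyStateError(
            f"oxygen field did not reach steady state in {max_outer} outer "
            f"iterations (last relative change {change:.3g})")
    # final consistent march for the deposition bookkeeping
    oxy, (nodes, g, cb, dep, ords) = _march_intravascular(net, tissue, chem, lpn)
    for o in np.unique(ords):
        supply[int(o)] = float(dep[ords == o].sum())
    co = tissue.reshape(lattice.shape)
    return OxygenResult(co, normalize_oxygen(co), oxy, supply, it)


def oxygen_point_source(net: VesselNetwork, o2_sink: np.ndarray,
                        chem: ChemConstants, lattice: LatticeSpec,
                        lap: sp.csr_matrix,
                        co_init: np.ndarray | None = None) -> OxygenResult:
    """Simplified oxygen model: every perfused vessel path node is a fixed
    concentration source at the inlet value (no advection, no trans-wall
    physics).  Used by the flow-independent ablation case."""
    n = lattice.n_nodes
    vol = lattice.spacing ** 3
    sink = np.asarray(o2_sink, dtype=float).ravel()
    segs = [s for s in net.active_segments() if abs(s.Q) > 1e-9]
    if not segs:
        z = np.zeros(lattice.shape)
        return OxygenResult(z, z.copy(), IntravascularOxygen(), {}, 0)
    # strong Robin coupling pins source nodes at the inlet concentration
    k_pin = 1.0e3 * chem.Do_um2 / lattice.spacing ** 2
    kappa = np.zeros(n)
    rhs = np.zeros(n)
    node_ord: dict[int, int] = {}
    for s in segs:
        for nd in s.node_path:
            kappa[nd] = k_pin
            rhs[nd] = k_pin * chem.inlet_o2
            node_ord[nd] = max(node_ord.get(nd, 0), s.order)
    x0 = None if co_init is None else np.asarray(co_init).ravel()
    A = (chem.Do_um2 * lap + sp.diags(kappa)).tocsr()
    mg = LatticeMultigrid(A, lattice.shape)
    tissue = _tissue_steady(A, mg, rhs, sink, x0, chem.o2_linear_crit)
    supply: dict[int, float] = {}
    for nd, o in node_ord.items():
        flux = kappa[nd] * (chem.inlet_o2 - tissue[nd]) * vol
        supply[o] = supply.get(o, 0.0) + max(flux, 0.0)
    oxy = IntravascularOxygen(
        {s.sid: np.full(len(s.node_path), chem.inlet_o2) for s in segs})
    co = tissue.reshape(lattice.shape)
    return OxygenResult(co, normalize_oxygen(co), oxy, supply, 1)


def diffuse_tissue_oxygen(co: np.ndarray, sink: np.ndarray, dt: float,
                          chem: ChemConstants, h: float) -> np.ndarray:
    """Explicit tissue oxygen diffusion-consumption step (no-flux
    boundaries, floored at zero, CFL sub-stepping)."""
    n, dts = _substeps(dt, chem.Do_um2, h)
    out = co
    for _ in range(n):
        out = out + dts * (chem.Do_um2 * laplacian_apply(out, h) - sink)
        out = np.maximum(out, 0.0)
    return out
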