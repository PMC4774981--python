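"""Simulation engine: the coupled macro-step loop and its outputs.

Each 1.5 h macro step runs, in order: (1) the coupled haemodynamic solve
and haematocrit distribution; (2) the quasi-steady chemical fields (ECM,
MDE, VEGF, three-domain oxygen); (3) the tumour-cell automaton sweep;
(4) vessel network updates in the fixed sub-order co-option/dilation and
permeability -> angiogenesis -> collapse-pressure and compliance ->
collapse checks.  A single seeded RNG stream drives every stochastic
choice in a frozen draw order (cell sweep, then sprout-tip events, then
collapse draws), so a (config, seed) pair reproduces a run bit for bit.

Ablation switches reproduce the model's own control experiments:
``C_a`` disables the migrating phenotype, ``C_b`` freezes wall
permeability and collapse pressure at their initial values, and ``C_c``
replaces the flow-dependent oxygen transport with fixed point sources on
every perfused vessel node.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemical_fields as cf
from . import haemodynamics as hd
from . import tumour_automaton as ta
from . import vessel_remodelling as vr
from .config import SimulationConfig
from .vascular_network import (VesselNetwork, assign_initial_state,
                               generate_network, write_network)

ABLATION_CASES = ("C_a", "C_b", "C_c")


class EngineError(RuntimeError):
    pass


@dataclass
class RunResult:
    config: SimulationConfig
    curves: pd.DataFrame
    events: pd.DataFrame
    net: VesselNetwork
    grid: ta.CellGrid
    summary: dict
    out_dir: str | None = None


@dataclass
class Simulation:
    """Mutable simulation state; use :func:`run` for the one-shot API."""

    config: SimulationConfig
    net: VesselNetwork | None = None
    grid: ta.CellGrid | None = None
    rng: np.random.Generator | None = None
    step_index: int = 0
    tips: list[vr.SproutTip] = field(default_factory=list)
    curves_rows: list[dict] = field(default_factory=list)
    event_rows: list[dict] = field(default_factory=list)
    seed_centroid: np.ndarray | None = None
    cf_field: np.ndarray | None = None
    cm_field: np.ndarray | None = None
    cv_field: np.ndarray | None = None
    co_raw: np.ndarray | None = None
    co_norm: np.ndarray | None = None
    pi_prev: np.ndarray | None = None
    f0: float = 0.0
    n_pre_existing: int = 0
    _lap = None

    # -- step 0 ------------------------------------------------------------
    def initialize(self) -> None:
        cfgv = self.config
        lat = cfgv.lattice
        self.rng = np.random.default_rng(cfgv.seed)
        if cfgv.network_file:
            from .vascular_network import assign_strahler, read_network
            self.net = read_network(cfgv.network_file)
            if self.net.lattice.shape != lat.shape:
                raise EngineError("network file lattice does not match the "
                                  "configured lattice")
            if any(s.order == 0 for s in self.net.segments):
                assign_strahler(self.net)
                assign_initial_state(self.net, cfgv.network, cfgv.remodel.LpN_um)
        else:
            self.net = generate_network(lat, cfgv.network, seed=cfgv.seed)
            assign_initial_state(self.net, cfgv.network, cfgv.remodel.LpN_um)
        self.net.inlet_haematocrit = cfgv.fluid.inlet_haematocrit
        for s in self.net.segments:
            s.H = cfgv.fluid.inlet_haematocrit
        self.n_pre_existing = len(self.net.segments)
        self.grid = ta.CellGrid(lat)
        if cfgv.n_initial_cells > 0:
            seeded = ta.seed_initial_cells(
                self.grid, self.net, cfgv.n_initial_cells, cfgv.placement,
                self.rng, cfgv.phenotype,
                explicit_nodes=cfgv.explicit_seed_nodes or None)
            xyz = np.array([lat.coords(int(x)) for x in seeded])
            self.seed_centroid = xyz.mean(axis=0)
        else:
            self.seed_centroid = np.array(lat.extent) / 2.0
        n = lat.n_nodes
        self.cf_field = np.ones(n)
        self.cm_field = np.zeros(n)
        self.cv_field = np.zeros(n)
        self.co_raw = np.zeros(n)
        self.co_norm = np.zeros(n)
        self._lap = hd.neumann_laplacian(lat)
        self.step_index = 0

    # -- one macro step ------------------------------------------------------
    def step(self) -> dict:
        cfgv = self.config
        lat = cfgv.lattice
        fl, ch, ph, rm = cfgv.fluid, cfgv.chem, cfgv.phenotype, cfgv.remodel
        net, grid, rng = self.net, self.grid, self.rng
        self.step_index += 1
        t = self.step_index
        try:
            # --- 1. haemodynamics ----------------------------------------
            for s in net.active_segments():
                s.mu = hd.blood_viscosity(2 * s.R, s.H, fl.plasma_viscosity)
            if not hasattr(self, "_mg_caches") or self._mg_caches is None:
                self._mg_caches = {"pi": {}, "o2": {}}
            sol = hd.solve_coupled_flow(
                net, fl, lat, pi_init=self.pi_prev, tol=cfgv.flow_tol,
                max_iter=cfgv.max_coupling_iter, under_relax=cfgv.under_relax,
                lap=self._lap, mg_cache=self._mg_caches["pi"])
            self.pi_prev = sol.Pi.ravel().copy()
            self._last_sol = sol
            hd.propagate_haematocrit(net)
            try:
                self.f0 = (hd.reference_wss_f0(net)
                           if (rm.recompute_f0 or self.f0 == 0.0) else self.f0)
            except hd.FlowError:
                pass    # keep the previous reference when order 3 is gone

            # --- 2. chemical fields --------------------------------------
            mde_src, vegf_src, vegf_sink, o2_sink = ta.phenotype_sources(
                grid, ch, ph)
            if not hasattr(self, "_chem_cache") or self._chem_cache is None:
                self._chem_cache = {}
            self.cm_field = cf.steady_reaction_diffusion(
                ch.Dm_um2, ch.lambda_mde, mde_src, lat, self._lap,
                x0=self.cm_field, rtol=cfgv.linear_rtol,
                cache=self._chem_cache).ravel()
            xi_eff = ch.xi * ch.chi
            self.cv_field = cf.steady_reaction_diffusion(
                ch.Dv_um2, ch.theta_vegf_decay,
                vegf_src + xi_eff * self.cf_field - vegf_sink, lat,
                self._lap, x0=self.cv_field, rtol=cfgv.linear_rtol,
                cache=self._chem_cache).ravel()
            self.cf_field = cf.update_ecm(
                self.cf_field, self.cm_field, cfgv.dt_seconds, ch.delta_ecm)
            # warm start: linear extrapolation of the last two tissue fields
            co_prev = getattr(self, "_co_prev", None)
            if co_prev is not None and self.co_raw is not None:
                co_guess = np.maximum(self.co_raw + 0.5 * (self.co_raw - co_prev),
                                      0.0)
            else:
                co_guess = self.co_raw
            if cfgv.ablation == "C_c":
                oxy = cf.oxygen_point_source(net, o2_sink, ch, lat, self._lap,
                                             co_init=co_guess)
            else:
                oxy = cf.oxygen_to_steady(net, o2_sink, ch, lat, self._lap,
                                          rm.LpN_um, co_init=co_guess,
                                          mg_cache=self._mg_caches["o2"])
            self._co_prev = None if self.co_raw is None else self.co_raw.copy()
            self.co_raw = oxy.tissue.ravel()
            self.co_norm = oxy.normalized.ravel()

            # --- 3. tumour cells -----------------------------------------
            v_adj, v_axis = ta.vessel_adjacency(net, grid)
            cell_ev = ta.step_cells(
                grid, self.co_norm, ph, rng, v_adj, v_axis,
                migration_enabled=(cfgv.ablation != "C_a"))

            # --- 4. vessel network ---------------------------------------
            frac = vr.segment_tumour_fraction(net, grid)
            dilated = vr.co_opt_and_dilate(net, self.cv_field, frac, rm,
                                           cfgv.dt_hours)
            if cfgv.ablation != "C_b":
                for s in net.active_segments():
                    vr.update_permeability(s, rm)
            angio_ev = vr.angiogenesis_step(self.tips, net, self.cv_field,
                                            self.cf_field, grid, rm, rng,
                                            lat.spacing)
            if cfgv.ablation == "C_b":
                # frozen-wall control: neo-vessels get the frozen wall state
                for s in net.segments:
                    if s.is_neo and not s.collapsed:
                        s.Lp = rm.LpN_um
                        s.Pc = s.Pc_init
            crushed: list[int] = []
            for s in net.active_segments():
                if cfgv.ablation != "C_b":
                    vr.update_collapse_pressure(s, rm)
                pv_bar = 0.5 * (sol.Pv.get(s.j_from, fl.inlet_pressure)
                                + sol.Pv.get(s.j_to, fl.inlet_pressure))
                pi_bar = sol.pi_mean.get(s.sid)
                if pi_bar is None:
                    pi_bar = float(self.pi_prev[np.asarray(s.node_path)].mean())
                if vr.update_radius_compliance(s, pv_bar, pi_bar, rm):
                    vr.collapse_segment(s)
                    crushed.append(s.sid)
            wss_collapsed = vr.collapse_check(net, self.f0, frac, rm, rng)
        except Exception as e:
            raise EngineError(f"macro step {t} failed: {e}") from e

        for sid in dilated[:20]:
            self.event_rows.append({"step": t, "segment": sid,
                                    "event": "dilate", "value": np.nan})
        for sid in crushed:
            self.event_rows.append({"step": t, "segment": sid,
                                    "event": "collapse_compression",
                                    "value": np.nan})
        for sid in wss_collapsed:
            self.event_rows.append({"step": t, "segment": sid,
                                    "event": "collapse_wss", "value": np.nan})
        if angio_ev.anastomoses:
            self.event_rows.append({"step": t, "segment": -1,
                                    "event": "anastomosis",
                                    "value": angio_ev.anastomoses})

        row = self._record(sol, oxy, cell_ev, frac)
        return row

    # -- per-step bookkeeping ----------------------------------------------
    def _record(self, sol: hd.FlowSolution, oxy: cf.OxygenResult,
                cell_ev: ta.StepEvents, frac: dict[int, float]) -> dict:
        cfgv = self.config
        lat = cfgv.lattice
        net, grid = self.net, self.grid
        counts = grid.counts()
        active = net.active_segments()
        n_active = len(active)
        n_collapsed = sum(1 for s in net.segments if s.collapsed)
        n_neo = sum(1 for s in net.segments if s.is_neo and not s.collapsed)
        n_immature = sum(1 for s in active if s.maturity == "immature")

        # tumour-interior speeds
        t_nodes = grid.tumour_nodes()
        uv_med = ui_med = np.nan
        max_disp = 0.0
        if len(t_nodes):
            xyz = np.array([lat.coords(int(x)) for x in t_nodes])
            max_disp = float(np.linalg.norm(xyz - self.seed_centroid,
                                            axis=1).max())
            tum_segs = [s for s in active
                        if frac.get(s.sid, 0.0) >= 0.5 and abs(s.Q) > 1e-9]
            if tum_segs:
                uv_med = float(np.median(
                    [abs(s.Q) / (np.pi * s.R ** 2) for s in tum_segs]))
            ui = sol.interstitial_velocity(lat, cfgv.fluid.K_um2)
            ui_mag = np.sqrt((ui ** 2).sum(axis=0)).ravel()
            ui_med = float(np.median(ui_mag[t_nodes]))

        supply = oxy.supply_by_order
        supply_tot = sum(supply.values()) or np.nan
        row = {
            "step": self.step_index,
            "P": counts["P"], "Q": counts["Q"], "N": counts["N"],
            "M": counts["M"], "total": counts["total"], "EC": counts["EC"],
            "vessels_active": n_active, "vessels_collapsed": n_collapsed,
            "vessels_neo": n_neo, "vessels_immature": n_immature,
            "vessels_pre_existing": self.n_pre_existing,
            "tips": len(self.tips),
            "f0": self.f0,
            "divisions": cell_ev.divisions,
            "to_necrotic": cell_ev.to_necrotic,
            "to_quiescent": cell_ev.to_quiescent,
            "from_quiescent": cell_ev.from_quiescent,
            "to_migrating": cell_ev.to_migrating,
            "migrations": cell_ev.migrations,
            "cleared": cell_ev.cleared,
            "settled": cell_ev.settled,
            "uv_median_tumour": uv_med,
            "ui_median_tumour": ui_med,
            "max_displacement": max_disp,
            "o2_supply_o1": supply.get(1, 0.0) / supply_tot,
            "o2_supply_o2": supply.get(2, 0.0) / supply_tot,
            "o2_supply_o3": supply.get(3, 0.0) / supply_tot,
            "co_norm_mean": float(np.mean(self.co_norm)),
            "co_norm_min": float(np.min(self.co_norm)),
            "co_raw_max": float(np.max(self.co_raw)),
            "cv_mean": float(np.mean(self.cv_field)),
            "cm_mean": float(np.mean(self.cm_field)),
            "cf_mean": float(np.mean(self.cf_field)),
        }
        self.curves_rows.append(row)
        return row

    # -- checkpointing -------------------------------------------------------
    def save_checkpoint(self, path: str) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load_checkpoint(path: str) -> "Simulation":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def run(config: SimulationConfig, out_dir: str | Path | None = None,
        progress: bool = False) -> RunResult:
    """Execute a full simulation and optionally write the run directory
    (growth-curves CSV, event CSV, config, final network, VTK snapshots)."""
    if config.ablation is not None and config.ablation not in ABLATION_CASES:
        raise EngineError(f"unknown ablation case {config.ablation!r}")
    sim = Simulation(config)
    sim.initialize()
    for _ in range(config.max_steps):
        sim.step()
        if progress and sim.step_index % 10 == 0:
            r = sim.curves_rows[-1]
            print(f"step {r['step']:4d}  TC={r['total']:6d} "
                  f"vessels={r['vessels_active']:4d} neo={r['vessels_neo']:3d}")
    curves = pd.DataFrame(sim.curves_rows)
    events = pd.DataFrame(sim.event_rows,
                          columns=["step", "segment", "event", "value"])
    summary = summarize_curves(curves)
    result = RunResult(config=config, curves=curves, events=events,
                       net=sim.net, grid=sim.grid, summary=summary)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = config.to_dict()
        meta["config_hash"] = config.config_hash()
        import yaml
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)
        curves.insert(0, "config_hash", config.config_hash())
        curves.to_csv(out / "curves.csv", index=False)
        events.to_csv(out / "events.csv", index=False)
        write_network(sim.net, str(out / "network_final.txt"))
        if getattr(sim, "_last_sol", None) is not None:
            hd.flow_to_dataframe(sim.net, sim._last_sol).to_csv(
                out / "flow_final.csv", index=False)
        if config.write_vtk:
            from .vtkio import write_field_vtk, write_network_vtk
            write_network_vtk(sim.net, str(out / "network_final.vtk"))
            write_field_vtk(sim.co_norm.reshape(config.lattice.shape),
                            config.lattice, str(out / "oxygen_final.vtk"),
                            "oxygen_normalized")
            write_field_vtk(sim.pi_prev.reshape(config.lattice.shape),
                            config.lattice, str(out / "pi_final.vtk"),
                            "interstitial_pressure")
            write_field_vtk(sim.grid.occupant.reshape(config.lattice.shape)
                            .astype(float), config.lattice,
                            str(out / "cells_final.vtk"), "occupant")
        result.out_dir = str(out)
    return result


def run_ablation(config: SimulationConfig, case: str,
                 out_dir: str | Path | None = None) -> RunResult:
    """Run one of the control cases with otherwise identical conditions."""
    if case not in ABLATION_CASES:
        raise EngineError(f"unknown ablation case {case!r}; "
                          f"choose one of {ABLATION_CASES}")
    import dataclasses as dc
    cfg2 = SimulationConfig.from_dict(config.to_dict())
    cfg2.ablation = case
    return run(cfg2, out_dir=out_dir)


# ---------------------------------------------------------------------------
# Milestone summary
# ---------------------------------------------------------------------------

def angiogenesis_onset(curves: pd.DataFrame, frac: float = 0.05) -> int | None:
    """First step at which neo-vessels reach ``frac`` of all vessel
    segments (the 5% onset definition)."""
    tot = curves["vessels_active"] + curves["vessels_collapsed"]
    mask = curves["vessels_neo"] >= frac * tot
    hits = curves.loc[mask, "step"]
    return int(hits.iloc[0]) if len(hits) else None


def summarize_curves(curves: pd.DataFrame, min_total: int = 500) -> dict:
    """Milestone metrics recomputable from the growth-curves table alone."""
    out: dict = {}
    if curves.empty:
        return {"warning": "empty curves"}
    out["steps"] = int(curves["step"].iloc[-1])
    out["final_counts"] = {k: int(curves[k].iloc[-1])
                           for k in ("P", "Q", "N", "M", "total")}
    out["angiogenesis_onset"] = angiogenesis_onset(curves)
    ngq = curves.loc[curves["N"] > curves["Q"], "step"]
    out["first_step_N_gt_Q"] = int(ngq.iloc[0]) if len(ngq) else None
    va = curves["vessels_active"].to_numpy()
    dec = np.flatnonzero(np.diff(va) < 0)
    out["first_vessel_decrease"] = int(curves["step"].iloc[dec[0] + 1]) \
        if len(dec) else None
    grown = curves[curves["total"] >= min_total]
    if len(grown):
        q_frac = grown["Q"] / grown["total"]
        out["quiescent_fraction_mean"] = float(q_frac.mean())
    else:
        out["quiescent_fraction_mean"] = None
    out["max_displacement"] = float(curves["max_displacement"].max())
    mid = curves.iloc[len(curves) // 2]
    if np.isfinite(mid.get("uv_median_tumour", np.nan)) and \
            np.isfinite(mid.get("ui_median_tumour", np.nan)) and \
            mid["ui_median_tumour"] > 0:
        out["speed_ratio_mid_run"] = float(
            mid["uv_median_tumour"] / mid["ui_median_tumour"])
    else:
        out["speed_ratio_mid_run"] = None
    last = curves.iloc[-1]
    out["o2_supply_share"] = {o: float(last[f"o2_supply_o{o}"])
                              for o in (1, 2, 3)}
    out["pn_gap_final"] = int(last["P"] - last["N"])
    return out


def summarize(run_dir: str | Path) -> dict:
    """Milestone report for a completed (or partial) run directory."""
    out = Path(run_dir)
    curves_path = out / "curves.csv"
    if not curves_path.exists():
        return {"warning": f"no curves.csv under {out}"}
    curves = pd.read_csv(curves_path)
    return summarize_curves(curves)
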