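# gliosim

Coupled 3D simulation of early glioblastoma growth: pre-existing vessel
co-option, remodelling, collapse, incipient angiogenesis and blood
perfusion.

Glioblastoma starts out *avascular* in an unusually literal sense: rather
than first inducing new vessels, the tumour cells crawl along and engulf
the brain's existing microvasculature, destabilize it, and only turn to
angiogenesis once collapse-driven hypoxia leaves them no choice. The
characteristic histology — pseudopalisades, necrotic foci, perivascular
cuffs — emerges from that interplay of perfusion, oxygen and migration.
`gliosim` is a research simulator for exactly this phase, aimed at people
who study tumour–microenvironment coupling in silico and want every
feedback loop explicit and inspectable.

The model couples, on one 10 μm lattice:

* a **Strahler-ordered arteriolar forest** (orders 1–3; diameters 8/12/16
  μm, mean lengths 80/200/320 μm, collapse pressures 1.0/1.5/2.0 mmHg);
* **haemodynamics**: per-segment Poiseuille flow `Qv = πR⁴ΔPv/(8μΔl)`,
  Starling leakage `Qt = 2πRΔl·Lp(Pv − Pi − σT(πv − πi))`, Darcy
  interstitial flow `Ui = −K∇Pi` with `∇·Ui` sourced by the leakage,
  in-vitro tube-law viscosity `μ(D, H)` and empirical red-cell phase
  separation at bifurcations;
* **quasi-steady chemicals**: ECM degraded by MDEs, MDE and VEGF
  reaction–diffusion with phenotype-scaled cell sources, and three-domain
  oxygen (intravascular advection of free + haemoglobin-bound O₂ with
  Hill saturation, Fick trans-wall flux, tissue diffusion with cellular
  consumption);
* a **four-phenotype cellular automaton** — proliferating, quiescent,
  necrotic, migrating glioma cells — switching on normalized oxygen
  thresholds (θ_prol, θ_surv) and free space, with along-vessel migration
  bias;
* **vessel remodelling**: VEGF-triggered co-option and dilation
  (0.40 μm/h to R_max = 10 μm), wall permeability `Lp = LpT·R/R_max`,
  collapse pressure `Pc = Pc_min·LpT/Lp`, Netti compliance
  `R = R0((Pv − Pi + Pc)/E)^b`, wall-shear-driven collapse below
  `τ_crit = 0.5·f0`, and hybrid sprout-tip angiogenesis
  (motility/chemotaxis/haptotaxis).

Everything is generated in code — no external data. A run is fully
reproducible from `(config, seed)`.

## A worked example

`examples/` holds one short script per capability; each builds its own
input, runs one piece of the model and prints what it computes:

| script | shows |
| --- | --- |
| `01_build_vessel_network.py` | generating the Strahler forest |
| `02_blood_flow_and_pressure.py` | coupled flow + haematocrit on a tree |
| `03_oxygen_field.py` | three-domain oxygen around a capillary |
| `04_baseline_growth.py` | a reduced baseline growth run |
| `05_ablation_switches.py` | the C_a / C_b / C_c control cases |

Running `python examples/03_oxygen_field.py` prints:

```
steady after 6 outer iterations; supply by order: {1: 143115} (conc·μm³/s)

normalized O2 vs distance from the vessel (y direction, z = 15):
     0 μm:  0.69  -> proliferation
    20 μm:  0.16  -> quiescence/migration
    40 μm:  0.00  -> necrosis
    60 μm:  0.00  -> necrosis
```

i.e. a perfused capillary supports proliferation-grade oxygen only in its
immediate corona, a band of quiescence/migration one or two cells out,
and necrosis beyond — the penetration depth that shapes the perivascular
growth pattern and pseudopalisade rims in full runs.

A full simulation from Python:

```python
from gliosim import SimulationConfig, LatticeSpec, run

cfg = SimulationConfig(lattice=LatticeSpec(50, 50, 50, 10.0),
                       max_steps=120, seed=1)
cfg.network.n_trees = 1            # keep full-scale vessel density at 0.5 mm
res = run(cfg, out_dir="runs/baseline")
print(res.summary)                  # onset, milestones, Q fraction, ...
```

or from the shell: `gliosim run --seed 1 --out runs/baseline`, with
`gliosim ablate --case C_a ...` for the control cases and
`gliosim summarize runs/baseline` for the milestone report. Run
directories contain the growth-curves CSV, the vessel event log, the
exact config (with hash) and the final network as a plain-text edge
list; optional legacy-VTK snapshots open in ParaView.

## Layout

```
src/gliosim/
  config.py             all constants and the serializable SimulationConfig
  vascular_network.py   Strahler forest generation, ordering, edge-list I/O
  haemodynamics.py      Poiseuille/Starling/Darcy solve, viscosity, WSS,
                        phase separation
  chemical_fields.py    ECM, MDE, VEGF, three-domain oxygen
  tumour_automaton.py   four-phenotype cell lattice
  vessel_remodelling.py co-option, walls, collapse, sprout tips
  engine.py             the macro-step loop, ablations, summaries
  mg.py                 multigrid preconditioner for the lattice solvers
  fixtures.py           toy networks and fields for tests/examples
```

`docs/methods.md` documents the model equations as implemented, unit
conventions, every open design choice and the known limitations.
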