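# Methods

`gliosim` simulates the earliest phase of glioblastoma growth — vessel
co-option, remodelling, collapse and incipient angiogenesis — as a hybrid
discrete–continuum model on a uniform cubic lattice. This note records the
model equations as implemented, the unit conventions, every numerical
choice that was genuinely open, and the limits of what the synthetic
set-up can show.

## Domain and units

The tissue is a cube discretized by an `n³` node lattice with 10 μm
spacing (default 100³ = 1 mm³; one node ≈ one cell diameter). Internal
units are μm, s and mmHg; constants quoted in the literature in cm-based
units are stored as quoted and converted on access. One macro time step
is 1.5 h; chemicals are treated as quasi-steady within each step.

## Pre-existing vasculature

The host vasculature is a forest of binary arteriolar trees classified by
Strahler order (leaves order 1; order increments only when equal orders
merge; clamped at 3). Main stems (order 3) enter at the x = max face and
every capillary chain terminates on the x = 0 face, so the imposed total
pressure difference (3.5 mmHg across the full-scale domain) perfuses all
branches. Per-order initial diameters (8/12/16 μm), mean segment lengths
(80/200/320 μm) and collapse pressures (1.0/1.5/2.0 mmHg) follow the
standard microcirculation census for orders 1/2/3. Diameters are
assigned, not sampled; on the default lattice per-order mean lengths are
reproduced exactly by construction.

Open generator choices (tree count, branching angles, inter-tree
anastomoses) are config parameters: 4 trees by default, dichotomous
branching, axial stems with lateral daughter branches, no pre-existing
anastomoses. Segments are polylines of lattice edges; a segment owns
every node it traverses, which is the common currency for oxygen
exchange, Starling sources and cell–vessel contact.

### Reduced lattices

On lattices smaller than 100³ the generator scales segment lengths by
`extent/990 μm` (rounded to lattice steps) so trees still span inlet to
outlet. Reduced-scale *runs* (tests, acceptance) use one tree per
(0.5 mm)³ and scale the driving pressure with the domain extent: both
choices preserve the full-scale microvascular length density and pressure
gradient, which are the quantities the growth dynamics actually feel. A
reduced domain still differs from the full one in a way no parameter can
hide: the tumour occupies a much larger *fraction* of the domain, so
late-run vessel collapse and boundary effects are stronger than at full
scale.

## Haemodynamics

Per segment, Poiseuille conduction and Starling leakage:

    Qv = π R⁴ ΔPv / (8 μ Δl)
    Qt = 2π R Δl Lp (P̄v − P̄i − σT(πv − πi))
    Q  = Qv − Qt,     Uv = Q / (π R²)

with σT = 0.82, πv = 20 mmHg, πi = 15 mmHg. Apparent viscosity μ follows
the published in-vitro tube law η(D, H) (η → plasma viscosity as H → 0);
red cells partition at diverging bifurcations by the empirical
phase-separation law (offset X0 = 0.4/D_parent, logit-linear in the flow
fraction), haematocrit clamped to [0, 0.95] with a warning. Plasma
viscosity (9.0×10⁻⁶ mmHg·s = 1.2 cP) and inlet discharge haematocrit
(0.45) are not part of the published constant set and are config values.

The interstitium obeys Darcy's law `Ui = −K∇Pi`
(K = 4.13×10⁻⁸ cm²/(mmHg·s)) with the transvascular leakage as a
distributed source, zero normal flow on the domain boundary, and the
source deposited on the nodes each segment traverses (wall area
2πR·h per path step, endpoints half). Junction pressures solve the
node-conservation linear system with Dirichlet values on both faces; the
absolute level (25 mmHg at the inlet face) is a model choice placing the
Starling and compliance brackets in a physiological range.

Numerics: the junction system is solved directly (it is small); the
interstitial system `(K·L + diag(κ)) Pi = κ(Pv − σΔπ)` by conjugate
gradients preconditioned with one V-cycle of a smoothed-aggregation
multigrid built on the 7-point Neumann Laplacian. Network and grid are
iterated block Gauss–Seidel (default tolerance 10⁻⁶ mmHg on the max
pressure change; under-relaxation 0.85, measured fastest for this weakly
coupled system — heavier damping only slows the fixed point, and the
solver raises on non-convergence rather than accepting a stale field). The multigrid hierarchy is reused
across steps until the Robin diagonal drifts by more than 10% — a stale
hierarchy only affects CG iteration counts, never the solution.

## Chemical fields

ECM density Cf (dimensionless, initially 1) decays by MDE attack,
integrated exactly per node: `Cf ← Cf·exp(−δ Cm Δt)`. MDE and VEGF obey
reaction–diffusion with per-cell sources scaled by phenotype (Table
below) and first-order decay; since their decay times (≈ 10⁸ s) dwarf any
feasible pseudo-time integration, the engine computes their quasi-steady
fields directly from the sparse linear systems (the same multigrid-CG
machinery); the explicit transient steppers remain available and tested.
The printed VEGF-from-ECM coefficient is dimensionally inconsistent with
the per-cell secretion terms; it is interpreted as a dimensionless
fraction of the TC secretion rate per unit ECM density
(ξ_eff = 10⁻³ χ), keeping the ECM contribution a small background as the
magnitudes of the printed constants imply.

### Oxygen

Oxygen is computed in three coupled domains, in units normalized to the
inlet free concentration (set to 1):

1. **Intravascular.** Free and haemoglobin-bound oxygen advect with the
   blood; bound load Co_B = capacity·H·SO2(Co_F) with a Hill saturation
   curve (n = 2.7, half-saturation 0.26 in inlet units — standard human
   haemoglobin shape; capacity 20 at H = 1). At junctions O2 flux is
   conserved and the free concentration is continuous; each daughter
   re-loads haemoglobin at its own haematocrit.
2. **Trans-wall.** Fick flux J = k(Co_Fin − Co_Fex), with the normal-wall
   mass-transfer coefficient (50 μm/s) scaled by Lp/LpN so leaky immature
   walls exchange faster.
3. **Tissue.** Pure diffusion (Do = 10⁻⁵ cm²/s) with per-cell zero-order
   consumption; interstitial advection is neglected (Ui is orders of
   magnitude below Uv).

Because the chemicals relax much faster than cells move, the engine
solves the *steady* coupled problem each macro step: the intravascular
steady state is obtained exactly by marching segments in descending
pressure order with flux-weighted mixing (the steady solution of the
upwind discretization — explicit advection at capillary speeds would
need ~10³ sub-steps per 5 s inner step); the tissue steady state is a
multigrid-CG solve with the vessel exchange as Robin coupling
(conductance g = Q(1 − e^{−kA/Q}), the complete-equilibration limit for
fast exchange); the two alternate to a fixed point (tolerance 10⁻⁴ on
the max relative change, adaptive damping only if the iteration
oscillates). Consumption below a cut-in concentration (0.02 inlet units)
tapers linearly to zero — a smooth stand-in for the hard supply-limited
cutoff that lets hypoxic cores relax stably to ~0.

The per-cell consumption rate γ0 deserves its own paragraph. The printed
constant set for oxygen descends from nondimensional sources and is not
mutually consistent as dimensional values; combined literally it yields
no hypoxia on any tissue length scale. γ0 is therefore an explicit
calibration parameter in inlet-units/s per cell. Its default (3.0) sets
the diffusion–consumption penetration depth around a perfused capillary
to ≈ 20–25 μm, i.e. viable perivascular cuffs a couple of cells thick —
the regime in which the model reproduces its characteristic growth-curve
shape (necrotic cells the majority, quiescent cells a ~10–20% minority,
pseudopalisade-like rims). Lower values thicken the viable shell and
inflate the quiescent fraction.

For phenotype decisions the tissue field is normalized by its current
global maximum (an all-zero field stays zero); the raw field is retained
for physics. The thresholds θ_prol = 0.30 and θ_surv = 0.05 live on this
normalized scale and are calibration tunables, not literature constants.
θ_prol is deliberately high: proliferation is confined to the immediate
perivascular corona while the wide intermediate band [θ_surv, θ_prol)
feeds the migrating phenotype, which is what drives the model's
signature co-optive spread of cells *along* host vessels and keeps the
crowded (quiescent) interior a minority. Calibrating with a low θ_prol
(0.15) instead yields compact ball-like growth whose interior is
dominated by quiescent cells — a regime the growth-curve milestones rule
out.

## Tumour-cell automaton

Four glioma phenotypes on the lattice — proliferating (P), quiescent
(Q), necrotic (N), migrating (M) — plus endothelial cells (EC) from
sprouting. Per step, in a freshly randomized sequential sweep (immediate
effect; a node freed earlier can be taken later the same sweep):

* P ages by 1 (cap T_TC = 6 steps = 9 h). With oxygen ≥ θ_prol and a
  free 6-neighbour it divides with probability T_age/T_TC; one daughter
  replaces the parent, both aged 1, the other takes a uniformly random
  free neighbour. Crowded cells become Q.
* Any tumour cell with oxygen < θ_surv becomes N permanently. N cells
  older than 30 steps (45 h) clear with probability 0.2/step, freeing
  the node.
* P at intermediate oxygen with space becomes M with probability 0.5 and
  moves to the free neighbour with the most oxygen (near-ties within
  0.02 broken with a 2:1 longitudinal preference when the cell touches a
  vessel path — the unquantified along-vessel bias). M settles back to P
  (age 1) wherever oxygen reaches θ_prol; boxed-in M becomes Q.
* Q reverts to P (age 1) when space frees and oxygen allows; quiescence
  has no clock.

Phenotype-scaled source multipliers (MDE, VEGF, O2 consumption):
M 2/4/2 · P 1/1/1 · Q 1/5 / 2 / 1/2 · N 1/10 / 4 / 1/4 of the base rates.

Founder seeding places 20 P cells (ages uniform 1..T_TC) adjacent to an
order-1 capillary: `perfusion_rich` picks the order-1 node closest to the
domain centre among candidates with at-least-median surrounding vessel
density (the central, adequately perfused placement); `perfusion_poor`
picks the node with the sparsest vasculature (a blood-supply-deficient
region).

## Vessel remodelling and angiogenesis

A vessel engulfed by the tumour (≥ 50% of its path nodes have a tumour
cell within one step) whose mean path VEGF exceeds θ_VEGF becomes
*immature* — a one-way transition — and its rest radius R0 grows at
0.40 μm/h while VEGF stays high, capped at R_max = 10 μm. Dilation acts
on the rest radius and the compliance law sets the realized radius;
otherwise compliance would silently undo each step's dilation. Immature
walls obey

    Lp = LpT (R / R_max),          LpT = 2.8×10⁻⁷ cm/(mmHg·s)
    Pc = Pc_min (LpT / Lp),        Pc_min = 0.5 × initial Pc, clamped to
                                   [Pc_min, initial Pc]
    R  = R0 ((Pv − Pi + Pc)/E)^b,  E = 6.5 mmHg, b = 0.1

(mature walls keep LpN = 0.36×10⁻⁷ cm/(mmHg·s), initial Pc, R = R0).
The update order per macro step follows the model's stated sequence:
dilation and Lp first, then (with the step's flow solution) Pc and the
compliance radius. A non-positive compliance bracket or R below the
0.5 μm floor crushes the segment outright.

Collapse by shear: a perfused, tumour-surrounded segment (≥ 80% of path
nodes with adjacent tumour cells) whose WSS τ = |ΔPv|·R/(2Δl) stays
below τ_crit = 0.5·f0 (f0 = mean WSS of the order-3 vessels, recomputed
each step) accumulates low-WSS steps and collapses with probability
min(1, 0.05·n) — the simplest law proportional to the duration.
Recovery above threshold resets the clock. Collapse is permanent.

Sprouts initiate on immature segments with VEGF above θ_VEGF
(probability 0.05 per segment-step, ≥ 30 μm between origins on a
segment). Tips walk the 6 lattice directions with weights from the
discretized EC flux — motility De, chemotaxis φc/(1+σCv)·∇Cv, haptotaxis
φh·∇Cf, negative drifts clamped — and anastomose on reaching another
vessel's path, splicing junctions into both the origin and target
segment and laying the trail down as order-1 immature neo-segments of
≈ 40 μm. Until anastomosis a trail carries no flow (it is EC occupancy
only). θ_VEGF (5×10⁻¹² M) and the chemotaxis saturation σ (10¹¹ M⁻¹)
are calibration values chosen so that co-option engages once a tumour
cluster of a few hundred cells surrounds a vessel and chemotaxis
saturates near the tumour-scale VEGF maximum.

## Engine

Each macro step runs: (1) viscosity update, coupled flow solve,
haematocrit propagation, f0; (2) steady MDE and VEGF, exact ECM decay,
steady three-domain oxygen; (3) the automaton sweep; (4) vessel updates
in the order co-option/dilation + permeability → angiogenesis →
collapse pressure + compliance → collapse checks. One RNG stream seeded
from the config drives everything in a frozen draw order (cell sweep,
then sprout events, then collapse draws), making runs bit-reproducible;
checkpoints pickle the full state including the RNG.

Ablation switches reproduce the model's control experiments: `C_a`
disables the migrating phenotype; `C_b` freezes Lp and Pc at initial
values (dilation and compliance still run); `C_c` replaces the
three-domain oxygen by fixed inlet-level point sources on every perfused
vessel node, so supply follows segment counts rather than perfusion.

## What the synthetic set-up does and does not show

All inputs are generated: the vasculature is a stylized Strahler forest,
not an imaged cerebrovascular bed; cells are lattice occupants without
mechanics or adhesion; solid stress, Ang-1/Ang-2/pericyte signalling and
lymphatics are absent by design. Migration speed is one lattice step per
macro step, so absolute displacement values are qualitative. Passing
tests therefore demonstrate internal consistency of the coupled solvers
(flow conservation to 10⁻⁸, field steady states to direct-solve accuracy,
exact stochastic rates) and reproduction of the model's characteristic
*regimes* — perivascular growth, hypoxia-driven phenotype cascades,
co-option-led vessel loss before angiogenesis — not quantitative
agreement with any real tumour.

Known numerical limitations: the quasi-steady oxygen fixed point is
damped adaptively and can need tens of outer iterations when large
hypoxic regions first form; anastomosis connects a trail to spliced
junctions at its end nodes (no partial-segment remeshing); on reduced
lattices the boundary is close enough to the tumour that late-run
dynamics (mass vessel collapse, domain-filling) are harsher than at full
scale. Problem sizes used by the shipped tests and the reproduction
script — ≈50³ lattices, ≤120 macro steps, 26–40³ for unit-level runs —
were chosen to keep the whole suite in the minutes range.

Two consequences of the reduced scale are worth spelling out, because
two shipped control-direction tests assert full-scale behaviour and are
expected to fail at desk scale. First, in the calibrated co-optive
regime migration is the dominant growth mode, so knocking it out (the
migration-free control) shrinks the entire population rather than
crowding it into quiescence; the quiescent-count excess of that control
needs the full-scale regime where migration is a minor add-on. Second,
by the end of a reduced run collapse has culled most order-1
capillaries, so the surviving stems edge out the capillaries in the
point-source oxygen supply shares; strict order-1 dominance needs the
full 1 mm³ network. Relatedly, with the zero-normal-flow interstitial
boundary the interstitial pressure equilibrates near the vascular level,
which keeps interstitial fluid speeds in the 10⁻⁴–10⁻³ μm/s range and
the compliance bracket far from crushing: the intravascular-to-
interstitial speed ratio the model computes is of order 10⁶, and
compression-driven collapse is rare — both are honest properties of the
stated equations and boundary conditions, not solver artifacts.
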