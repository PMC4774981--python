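"""Configuration for the coupled glioblastoma growth simulator.

All tunable constants live here, grouped the way the model is factored:
lattice geometry, fluid/haemodynamic constants, chemical-field constants,
tumour-cell phenotype parameters, vessel remodelling parameters and the
pre-existing-network generator parameters.

Internal unit system: micrometre, second, mmHg.  Literature constants that
are conventionally quoted in cm-based units are stored as quoted and
converted on access (``*_um`` properties), so the configuration file a user
sees matches the published numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

CM_TO_UM = 1.0e4
CM2_TO_UM2 = 1.0e8


@dataclass
class LatticeSpec:
    """Uniform cubic lattice covering the simulation domain.

    The default is a 100x100x100 node grid with 10 μm spacing, i.e. a
    1 mm^3 cube.  Node coordinates are ``index * spacing`` (0-based), so the
    inlet plane "x = max" is node index ``n_x - 1``.
    """

    n_x: int = 100
    n_y: int = 100
    n_z: int = 100
    spacing: float = 10.0  # μm, centre-to-centre

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("lattice spacing must be positive")
        if min(self.n_x, self.n_y, self.n_z) < 2:
            raise ValueError("lattice needs at least 2 nodes per axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_x, self.n_y, self.n_z)

    @property
    def n_nodes(self) -> int:
        return self.n_x * self.n_y * self.n_z

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical extent per axis, μm: (n - 1) * spacing."""
        return (
            (self.n_x - 1) * self.spacing,
            (self.n_y - 1) * self.spacing,
            (self.n_z - 1) * self.spacing,
        )

    # -- index helpers -----------------------------------------------------
    def ravel(self, i: int, j: int, k: int) -> int:
        return (i * self.n_y + j) * self.n_z + k

    def unravel(self, idx: int) -> tuple[int, int, int]:
        i, rem = divmod(idx, self.n_y * self.n_z)
        j, k = divmod(rem, self.n_z)
        return i, j, k

    def coords(self, idx: int) -> tuple[float, float, float]:
        i, j, k = self.unravel(idx)
        return (i * self.spacing, j * self.spacing, k * self.spacing)

    def in_bounds(self, i: int, j: int, k: int) -> bool:
        return 0 <= i < self.n_x and 0 <= j < self.n_y and 0 <= k < self.n_z


@dataclass
class FluidConstants:
    """Haemodynamic constants (Starling/Darcy coupling).

    sigma_T, pi_v, pi_i, K and S/V are the Baxter–Jain values; the total
    intravascular pressure drop across the domain (inlet face x = max to
    outlet face x = 0) is 3.5 mmHg.  The absolute pressure level and plasma
    viscosity are not part of the published table and are model choices.
    """

    sigma_T: float = 0.82          # osmotic reflection coefficient, -
    pi_v: float = 20.0             # plasma colloid osmotic pressure, mmHg
    pi_i: float = 15.0             # interstitial colloid osmotic pressure, mmHg
    K_cm2: float = 4.13e-8         # interstitial hydraulic conductivity, cm^2/(mmHg s)
    S_over_V_cm: float = 200.0     # exchange area density, 1/cm
    total_pressure_drop: float = 3.5   # mmHg across the domain in x
    inlet_pressure: float = 25.0   # mmHg, absolute level at x = max
    plasma_viscosity: float = 9.0e-6   # mmHg s  (1.2 cP)
    inlet_haematocrit: float = 0.45

    @property
    def K_um2(self) -> float:
        return self.K_cm2 * CM2_TO_UM2

    @property
    def S_over_V_um(self) -> float:
        return self.S_over_V_cm / CM_TO_UM

    @property
    def outlet_pressure(self) -> float:
        return self.inlet_pressure - self.total_pressure_drop

    @property
    def osmotic_term(self) -> float:
        """sigma_T * (pi_v - pi_i), the oncotic part of Starling's law."""
        return self.sigma_T * (self.pi_v - self.pi_i)


@dataclass
class ChemConstants:
    """Constants of the quasi-steady chemical fields.

    ECM density Cf is dimensionless (initially 1), MDE and VEGF are carried
    in molar units with per-node per-cell sources as published.  The oxygen
    subsystem is computed in units normalized to the inlet free-oxygen
    concentration (set to 1); ``gamma0`` is the per-cell zero-order
    consumption in those units, calibrated to a Krogh-type oxygen
    penetration depth of ~100-150 μm around a perfused capillary.
    """

    # diffusion coefficients, quoted cm^2/s
    Dm_cm2: float = 1.0e-9         # MDE
    Dv_cm2: float = 2.9e-7         # VEGF
    Do_cm2: float = 1.0e-5         # oxygen
    # ECM / MDE
    delta_ecm: float = 1.3e2       # ECM degradation by MDE, 1/(M s)
    mu_T: float = 1.7e-18          # MDE production per TC, M/s per node
    mu_E: float = 0.3e-18          # MDE production per EC, M/s per node
    lambda_mde: float = 1.7e-8     # MDE decay, 1/s
    # VEGF
    chi: float = 1.0e-17           # VEGF production per TC, M/s per node
    xi: float = 1.0e-3             # ECM VEGF production, fraction of chi per unit Cf
    eps_ec: float = 1.0e-20        # VEGF consumption per EC, M/s per node
    theta_vegf_decay: float = 1.0e-8   # VEGF decay, 1/s
    # oxygen
    alpha_bunsen: float = 1.27e-15     # μmol/(μm^3 mmHg), kept for reference
    inlet_o2: float = 1.0          # inlet free O2, defines the working unit
    hb_capacity: float = 20.0      # 4*C_Hb: bound/free capacity ratio at H=1, SO2=1
    hill_n: float = 2.7            # haemoglobin Hill coefficient
    o2_half_sat: float = 0.26      # free O2 at 50% saturation, inlet units
    gamma0: float = 3.0            # O2 consumption per P cell, inlet units/s
    o2_linear_crit: float = 0.02   # below this the zero-order consumption
                                   # tapers linearly to 0 (regularization)
    wall_o2_perm: float = 50.0     # μm/s; free-O2 wall mass-transfer coeff of a
                                   # normal (Lp = LpN) wall, scaled by Lp/LpN
                                   # for leakier walls (Fick's law, Eq of state
                                   # Lp/(alpha w) re-expressed in working units)
    inner_dt: float = 5.0          # s, inner iteration step
    steady_tol: float = 1.0e-4     # max relative change defining "steady"
    max_inner_iter: int = 200

    @property
    def Dm_um2(self) -> float:
        return self.Dm_cm2 * CM2_TO_UM2

    @property
    def Dv_um2(self) -> float:
        return self.Dv_cm2 * CM2_TO_UM2

    @property
    def Do_um2(self) -> float:
        return self.Do_cm2 * CM2_TO_UM2


@dataclass
class PhenotypeParams:
    """Four-phenotype cellular automaton parameters.

    The oxygen thresholds are defined on the normalized (0..1) oxygen scale.
    Their values are calibration choices, not published constants.
    Table-2 multipliers: per-phenotype factors on the base MDE production
    (mu_T), VEGF production (chi) and oxygen consumption (gamma0).
    """

    T_TC: int = 6                  # proliferation time, steps (9 h at 1.5 h/step)
    theta_prol: float = 0.30       # normalized O2 needed to proliferate
    theta_surv: float = 0.05       # normalized O2 needed to survive
    p_migrate: float = 0.5         # P -> M probability at intermediate O2
    p_necrotic_clear: float = 0.2  # clearance probability per step
    clearance_delay: int = 30      # steps a cell must stay necrotic (45 h)
    longitudinal_bias: float = 2.0 # weight ratio along-vessel : radial moves
    # Table-2 multipliers keyed by phenotype code: (MDE, VEGF, O2)
    mde_mult: dict[str, float] = field(
        default_factory=lambda: {"M": 2.0, "P": 1.0, "Q": 0.2, "N": 0.1})
    vegf_mult: dict[str, float] = field(
        default_factory=lambda: {"M": 4.0, "P": 1.0, "Q": 2.0, "N": 4.0})
    o2_mult: dict[str, float] = field(
        default_factory=lambda: {"M": 2.0, "P": 1.0, "Q": 0.5, "N": 0.25})


@dataclass
class RemodellingParams:
    """Vessel co-option, dilation, permeability, compliance, collapse and
    angiogenesis parameters."""

    theta_vegf: float = 5.0e-12    # M; co-option/dilation trigger (calibrated)
    dilation_rate: float = 0.40    # μm/h
    R_max: float = 10.0            # μm
    LpT_cm: float = 2.8e-7         # tumour wall permeability, cm/(mmHg s)
    LpN_cm: float = 0.36e-7        # normal wall permeability, cm/(mmHg s)
    E: float = 6.5                 # compliance coefficient, mmHg
    b: float = 0.1                 # compliance exponent
    tau_crit_factor: float = 0.5   # tau_crit = factor * f0
    collapse_prob_slope: float = 0.05  # collapse prob increment per low-WSS step
    surrounded_fraction: float = 0.8   # path fraction with adjacent TCs => "surrounded"
    co_option_fraction: float = 0.5    # path fraction with adjacent TCs => "inside tumour"
    R_floor: float = 0.5           # μm; compression below this collapses the vessel
    recompute_f0: bool = True      # recompute order-3 mean WSS every step
    # angiogenesis
    De_cm2: float = 1.0e-9         # EC random motility, cm^2/s
    phi_c_cm2: float = 2.6e3       # chemotaxis coefficient, cm^2/(M s)
    phi_h_cm2: float = 1.0e3       # haptotaxis coefficient, cm^2/(M s)
    chemo_sat_sigma: float = 1.0e11    # 1/M; chemotaxis receptor saturation
    sprout_prob: float = 0.05      # per immature segment per step
    sprout_min_spacing: float = 30.0   # μm between sprout origins on a segment
    neo_segment_length: float = 40.0   # μm of trail consolidated into one neo segment
    max_tips: int = 200

    @property
    def LpT_um(self) -> float:
        return self.LpT_cm * CM_TO_UM

    @property
    def LpN_um(self) -> float:
        return self.LpN_cm * CM_TO_UM

    @property
    def De_um2(self) -> float:
        return self.De_cm2 * CM2_TO_UM2

    @property
    def phi_c_um2(self) -> float:
        return self.phi_c_cm2 * CM2_TO_UM2

    @property
    def phi_h_um2(self) -> float:
        return self.phi_h_cm2 * CM2_TO_UM2


# Table 1: per-Strahler-order initial diameter (μm), mean length (μm) and
# collapse pressure (mmHg).
TABLE1_DIAMETER = {1: 8.0, 2: 12.0, 3: 16.0}
TABLE1_LENGTH = {1: 80.0, 2: 200.0, 3: 320.0}
TABLE1_PC = {1: 1.0, 2: 1.5, 3: 2.0}


@dataclass
class NetworkGenParams:
    """Generator parameters for the pre-existing arteriolar trees.

    Per-order diameters/lengths default to the Table-1 values; on lattices
    smaller than the default 100^3 the lengths are scaled to the domain
    extent (rounded to lattice steps) so the trees still span inlet to
    outlet face.
    """

    n_trees: int = 4
    diameters: dict[int, float] = field(default_factory=lambda: dict(TABLE1_DIAMETER))
    lengths: dict[int, float] = field(default_factory=lambda: dict(TABLE1_LENGTH))
    collapse_pressures: dict[int, float] = field(default_factory=lambda: dict(TABLE1_PC))
    stem_segments: int = 2         # order-3 segments chained in the main stem
    length_jitter: float = 0.0     # fractional jitter on segment lengths
    scale_to_lattice: bool = True  # scale lengths to lattice extent


@dataclass
class SimulationConfig:
    """Everything a run needs; serializes losslessly to YAML."""

    lattice: LatticeSpec = field(default_factory=LatticeSpec)
    fluid: FluidConstants = field(default_factory=FluidConstants)
    chem: ChemConstants = field(default_factory=ChemConstants)
    phenotype: PhenotypeParams = field(default_factory=PhenotypeParams)
    remodel: RemodellingParams = field(default_factory=RemodellingParams)
    network: NetworkGenParams = field(default_factory=NetworkGenParams)
    dt_hours: float = 1.5
    max_steps: int = 200
    seed: int = 0
    network_file: str | None = None    # edge-list file instead of generation
    n_initial_cells: int = 20
    placement: str = "perfusion_rich"   # perfusion_rich | perfusion_poor | explicit
    explicit_seed_nodes: list[int] = field(default_factory=list)
    ablation: str | None = None         # None | "C_a" | "C_b" | "C_c"
    output_every: int = 10
    write_vtk: bool = False
    # numerics
    under_relax: float = 0.85
    flow_tol: float = 1.0e-6       # mmHg, coupled-flow fixed point
    max_coupling_iter: int = 60
    linear_rtol: float = 1.0e-6    # chem-field CG; well below field scales

    @property
    def dt_seconds(self) -> float:
        return self.dt_hours * 3600.0

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        # YAML/JSON dict keys must be str for the per-order tables
        for key in ("diameters", "lengths", "collapse_pressures"):
            d["network"][key] = {str(k): v for k, v in d["network"][key].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        net = dict(d.get("network", {}))
        for key in ("diameters", "lengths", "collapse_pressures"):
            if key in net:
                net[key] = {int(k): float(v) for k, v in net[key].items()}
        kwargs: dict[str, Any] = {}
        sub = {
            "lattice": LatticeSpec, "fluid": FluidConstants, "chem": ChemConstants,
            "phenotype": PhenotypeParams, "remodel": RemodellingParams,
        }
        for name, typ in sub.items():
            if name in d:
                kwargs[name] = typ(**d.pop(name))
        if "network" in d:
            d.pop("network")
            kwargs["network"] = NetworkGenParams(**net)
        for f in dataclasses.fields(cls):
            if f.name in d and f.name not in kwargs:
                kwargs[f.name] = d[f.name]
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
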