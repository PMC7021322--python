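"""Simulation configuration: lattice, Potts, elasticity, VEGF and signaling parameters.

All defaults reproduce the published parameter tables of the model this package
implements (dimensionless Potts couplings; kPa-scale substrate elasticity;
molecules/hour signaling rates). Configurations round-trip losslessly through
JSON via :meth:`SimulationConfig.to_file` / :meth:`SimulationConfig.from_file`.

Unit conventions
----------------
* lengths: micrometres internally (``LatticeConfig.L`` is given in mm),
* times: hours,
* VEGF concentration: stored nondimensionally in units of the boundary
  concentration ``S`` (``c = C/S``); molecule-count conversions for signaling
  are centralized in :class:`VegfParameters`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal


class ConfigError(ValueError):
    """Raised for inconsistent or out-of-range configuration values."""


@dataclass
class LatticeConfig:
    """Square CPM domain: ``M x M`` nodes, ``(M-1)^2`` square pixels of side ``h``."""

    L_mm: float = 0.495     #: domain side length (mm)
    M: int = 199            #: nodes per side; pixel count is (M-1)^2
    T: float = 4.0          #: Potts temperature (energy units)

    def __post_init__(self) -> None:
        if self.M < 3:
            raise ConfigError("M must be >= 3")
        if self.L_mm <= 0:
            raise ConfigError("L must be positive")
        if self.T <= 0:
            raise ConfigError("Potts temperature must be positive")

    @property
    def h_um(self) -> float:
        """Node spacing h = L/(M-1) in micrometres."""
        return self.L_mm * 1000.0 / (self.M - 1)

    @property
    def n_pixels_side(self) -> int:
        return self.M - 1


@dataclass
class PottsParameters:
    """Dimensionless couplings of the CPM Hamiltonian."""

    rho_area: float = 9000.0
    rho_perimeter: float = 250.0
    rho_length: float = 7200.0
    rho_durot: float = 25.0
    rho_chem0: float = 60000.0
    rho_adh_cell_cell: float = 8.25
    rho_adh_cell_ecm: float = 16.50
    alpha_chem: float = 0.3          #: chemotaxis saturation
    adhesion_neighborhood: int = 2   #: 1 = von Neumann, 2 = Moore pairs
    connectivity_check: bool = True  #: reject flips that locally fragment a cell
    rho_persist_frac: float = 0.1    #: persistent-motion bonus, fraction of rho_chem0

    def __post_init__(self) -> None:
        for name in ("rho_area", "rho_perimeter", "rho_length", "rho_durot",
                     "rho_chem0", "rho_adh_cell_cell", "rho_adh_cell_ecm"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.adhesion_neighborhood not in (1, 2):
            raise ConfigError("adhesion_neighborhood must be 1 or 2")


@dataclass
class CellShapeTargets:
    """Target area/perimeter/length of one cell (um^2, um, um)."""

    area: float = 78.50
    perimeter: float = 31.4
    length: float = 49.5

    def __post_init__(self) -> None:
        if min(self.area, self.perimeter, self.length) <= 0:
            raise ConfigError("shape targets must be positive")


#: Non-proliferating cell targets.
TARGETS_NORMAL = CellShapeTargets(78.50, 31.4, 49.5)
#: Proliferating cells: double target area, triple perimeter, longer target length.
TARGETS_PROLIFERATING = CellShapeTargets(157.0, 94.2, 70.0)


@dataclass
class ElasticityParameters:
    """Plane-stress linear elasticity of the substrate."""

    E_kpa: float = 10.0      #: Young's modulus (kPa)
    nu: float = 0.45         #: Poisson ratio
    mu_force: float = 1.0    #: traction magnitude per unit node distance (N/m^2)

    def __post_init__(self) -> None:
        if not (0.0 <= self.nu < 0.5):
            raise ConfigError("Poisson ratio must satisfy 0 <= nu < 0.5")
        if self.E_kpa <= 0:
            raise ConfigError("Young's modulus must be positive")


@dataclass
class DurotaxisParameters:
    """Strain-stiffening sigmoid used by the durotaxis energy term."""

    E_theta_kpa: float = 15.0  #: threshold stiffness (kPa)
    E0_kpa: float = 10.0       #: base substrate stiffness (kPa)
    omega: float = 0.5         #: sigmoid steepness (1/kPa)
    eps_st: float = 0.1        #: stiffening strain scale

    def __post_init__(self) -> None:
        if min(self.E_theta_kpa, self.E0_kpa, self.omega, self.eps_st) <= 0:
            raise ConfigError("durotaxis parameters must be positive")


@dataclass
class VegfParameters:
    """Reaction-diffusion VEGF field with cellular uptake.

    The field is evolved nondimensionally, ``c = C/S``.  ``S_molec`` sets the
    molecule-count equivalent of the boundary concentration S used when the
    signaling module samples the field (``V_ext = chi_V * S_molec * c``).
    """

    D_f_mm2_h: float = 0.036     #: diffusivity (mm^2/h)
    nu_decay: float = 0.6498     #: decay rate (1/h)
    S_g_um2: float = 5e-19       #: boundary concentration (g/um^2)
    Gamma_pg_um2_h: float = 0.02 #: max cell uptake (pg/(um^2 h))
    upsilon: float = 1.0         #: uptake rate (1/h)
    #: molecule count corresponding to c = 1 (the boundary concentration S);
    #: the external-VEGF scale is 6 V_0 = 1200 molecules and cells near the
    #: hypoxic edge see about six such units, hence 7200
    S_molec: float = 7200.0
    scheme: Literal["implicit", "explicit"] = "implicit"

    def __post_init__(self) -> None:
        for name in ("D_f_mm2_h", "nu_decay", "S_g_um2", "Gamma_pg_um2_h",
                     "upsilon", "S_molec"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    @property
    def D_um2_h(self) -> float:
        return self.D_f_mm2_h * 1.0e6

    @property
    def Gamma_c_units(self) -> float:
        """Saturated uptake rate expressed in c-units per hour (Gamma/S)."""
        return self.Gamma_pg_um2_h * 1e-12 / self.S_g_um2


@dataclass
class SignalingRates:
    """Production, interaction and degradation rates of the Notch pathway ODEs."""

    r_N: float = 1200.0   #: Notch production (molecules/h)
    r_D: float = 1000.0   #: Delta-4 production (molecules/h)
    r_J: float = 1000.0   #: Jagged-1 production (molecules/h)
    r_VR: float = 1000.0  #: VEGFR2 production (molecules/h)
    k_C: float = 5e-4     #: cis-inhibition rate ((h molecule)^-1)
    k_T: float = 2.5e-5   #: trans-activation rate ((h molecule)^-1)
    gamma: float = 0.1    #: degradation of N, D, J, VR (1/h)
    gamma_S: float = 0.5  #: degradation of NICD and internal VEGF (1/h)

    def __post_init__(self) -> None:
        if any(getattr(self, f.name) < 0 for f in dataclasses.fields(self)):
            raise ConfigError("signaling rates must be non-negative")


@dataclass
class HillParameters:
    """Fold-changes, exponents and thresholds of the shifted Hill gates."""

    lambda_I_N: float = 2.0
    lambda_I_D: float = 0.0
    lambda_I_J: float = 2.0
    lambda_I_VR: float = 0.0
    lambda_V_D: float = 2.0
    lambda_D_F: float = 3.0
    lambda_J_F: float = 0.3
    n_N: float = 2.0
    n_D: float = 2.0
    n_J: float = 5.0
    n_V: float = 2.0
    n_VR: float = 2.0
    n_F: float = 1.0
    I_0: float = 200.0    #: NICD activation number (molecules)
    V_0: float = 200.0    #: VEGF activation number (molecules)
    chi_V: float = 1.0    #: external-VEGF conversion factor

    def __post_init__(self) -> None:
        for name in ("n_N", "n_D", "n_J", "n_V", "n_VR", "n_F"):
            if getattr(self, name) < 1:
                raise ConfigError("Hill exponents must be >= 1")
        if self.I_0 <= 0 or self.V_0 <= 0:
            raise ConfigError("Hill thresholds must be positive")


@dataclass
class EventParameters:
    """Branching / proliferation / anastomosis bookkeeping constants."""

    incubation_mcts: int = 400        #: MCTS a new branch incubates
    psi_p: float = 1e-3               #: proliferation VEGF threshold (c-units of S)
    gap_distance_um: float = 10.0     #: one cell diameter; larger gaps are filled
    tip_fraction: float = 0.5         #: tip threshold, fraction of max_i V_i
    hybrid_fraction: float = 0.2      #: lower hybrid threshold, fraction of max_i V_i
    hybrids_branch: bool = True       #: hybrid cells may also seed new branches


@dataclass
class SimulationConfig:
    """Complete configuration of one simulation run."""

    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    potts: PottsParameters = field(default_factory=PottsParameters)
    elasticity: ElasticityParameters = field(default_factory=ElasticityParameters)
    durotaxis: DurotaxisParameters = field(default_factory=DurotaxisParameters)
    vegf: VegfParameters = field(default_factory=VegfParameters)
    rates: SignalingRates = field(default_factory=SignalingRates)
    hill: HillParameters = field(default_factory=HillParameters)
    events: EventParameters = field(default_factory=EventParameters)
    case: Literal["A", "B"] = "A"
    n_mcts: int = 1000
    #: physical duration of one MCTS (h); None resolves to the calibrated
    #: value for the chosen dynamics (0.044 for case A, 0.03 for case B)
    mcts_hours: float | None = None
    seed: int = 0
    fem_every: int = 1                  #: FEM refresh cadence (MCTS)
    signaling_substeps: int = 20        #: Euler substeps per MCTS
    snapshot_every: int = 50
    initial_column_width_px: int = 4    #: primary vessel width (pixels)
    initial_cell_rows_px: int = 3       #: rows of pixels per initial cell

    def __post_init__(self) -> None:
        if self.case not in ("A", "B"):
            raise ConfigError("case must be 'A' or 'B'")
        if self.mcts_hours is None:
            self.mcts_hours = 0.044 if self.case == "A" else 0.03
        if self.mcts_hours <= 0 or self.n_mcts < 0:
            raise ConfigError("invalid run length")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        for name, sub in (("lattice", LatticeConfig), ("potts", PottsParameters),
                          ("elasticity", ElasticityParameters),
                          ("durotaxis", DurotaxisParameters), ("vegf", VegfParameters),
                          ("rates", SignalingRates), ("hill", HillParameters),
                          ("events", EventParameters)):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub(**kwargs[name])
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def reduced_fixture(cls, **overrides) -> "SimulationConfig":
        """100 x 100-pixel test domain (~33 initial cells), h = 2.5 um."""
        kwargs: dict = dict(lattice=LatticeConfig(L_mm=0.25, M=101))
        kwargs.update(overrides)
        return cls(**kwargs)
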