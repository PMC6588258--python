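"""Parameter containers: the single source of truth for a simulation run.

Every symbol of the energy functions, threshold formulas and experiment
protocols lives here, with the calibrated baseline values as defaults.
Quantities the calibrated baseline table does not fix (adhesion matrix,
stiffnesses, diffusion constants, quiescent threshold multipliers) carry
documented surrogate defaults; all are overridable from a YAML config
file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Any

import numpy as np
import yaml


class CellType(IntEnum):
    """Cell types on the lattice. MEDIUM is the continuous stromal compartment."""

    MEDIUM = 0
    ECM = 1
    BASAL = 2
    PCANCER = 3
    PSTEM = 4
    QCANCER = 5
    QSTEM = 6
    NECROTIC = 7


N_TYPES = 8

#: the five discrete tumor types (counted in "tumor volume")
TUMOR_TYPES = (
    CellType.PCANCER,
    CellType.PSTEM,
    CellType.QCANCER,
    CellType.QSTEM,
    CellType.NECROTIC,
)
#: metabolically active tumor types
VIABLE_TYPES = (CellType.PCANCER, CellType.PSTEM, CellType.QCANCER, CellType.QSTEM)
PROLIFERATING_TYPES = (CellType.PCANCER, CellType.PSTEM)
QUIESCENT_TYPES = (CellType.QCANCER, CellType.QSTEM)
EPITHELIAL_TYPES = (CellType.ECM, CellType.BASAL)

SPECIES = ("glucose", "glutamine", "oxygen", "lactate")


def _default_J() -> np.ndarray:
    """Surrogate contact-energy matrix.

    Ordering encodes the qualitative statements the model relies on:
    tumor cells cohere (J(tumor,tumor) < J(tumor,Medium)), and necrotic
    cells are strongly repelled by stroma and epithelium so necrosis stays
    confined to the core.
    """
    J = np.zeros((N_TYPES, N_TYPES))
    M, E, B, PC, PS, QC, QS, NE = range(N_TYPES)
    tumor = (PC, PS, QC, QS)
    for a in tumor:
        for b in tumor:
            J[a, b] = 4.0
        J[a, M] = J[M, a] = 12.0
        J[a, E] = J[E, a] = 14.0
        J[a, B] = J[B, a] = 14.0
    for a in (E, B):
        for b in (E, B):
            J[a, b] = 3.0
        J[a, M] = J[M, a] = 8.0
    for a in tumor:
        J[NE, a] = J[a, NE] = 5.0
    J[NE, NE] = 5.0
    J[NE, M] = J[M, NE] = 25.0
    J[NE, E] = J[E, NE] = 25.0
    J[NE, B] = J[B, NE] = 25.0
    return J


def _default_lambda(epithelial: float, tumor: float) -> np.ndarray:
    lam = np.zeros(N_TYPES)
    lam[[CellType.ECM, CellType.BASAL]] = epithelial
    lam[[CellType.PCANCER, CellType.PSTEM, CellType.QCANCER, CellType.QSTEM,
         CellType.NECROTIC]] = tumor
    return lam


@dataclass
class EnergyConfig:
    """Hamiltonian coefficients for the Cellular Potts engine."""

    Tm: float = 10.0                      # membrane-fluctuation temperature
    lambda_v: np.ndarray = field(default_factory=lambda: _default_lambda(10.0, 2.0))
    lambda_s: np.ndarray = field(default_factory=lambda: _default_lambda(10.0, 2.0))
    J: np.ndarray = field(default_factory=_default_J)
    lambda_chem: float = 20.0             # one value for glucose/glutamine/oxygen
    lambda_fpp: float = 10.0              # focal-point link stiffness (ECM/Basal)
    fpp_target_length: float = 8.0        # rest length L_ij, voxels
    fpp_max_distance: float = 20.0        # links longer than this break
    volume_form: str = "quadratic"        # 'quadratic' (GGH convention) or 'linear'

    def validate(self) -> None:
        if self.Tm <= 0:
            raise ValueError(f"Tm must be > 0, got {self.Tm}")
        self.lambda_v = np.asarray(self.lambda_v, dtype=float)
        self.lambda_s = np.asarray(self.lambda_s, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if self.J.shape != (N_TYPES, N_TYPES):
            raise ValueError(f"J must be {N_TYPES}x{N_TYPES}")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("adhesion matrix J must be symmetric")
        if (self.lambda_v < 0).any() or (self.lambda_s < 0).any():
            raise ValueError("lambda_v / lambda_s must be non-negative")
        if self.lambda_chem < 0 or self.lambda_fpp < 0:
            raise ValueError("lambda coefficients must be non-negative")
        if self.volume_form not in ("quadratic", "linear"):
            raise ValueError(f"unknown volume_form {self.volume_form!r}")


@dataclass
class FieldConfig:
    """One extracellular species.

    ``G_baseline_mM`` is the no-tumor steady concentration G(x); the uniform
    secretion rate follows alpha = epsilon * G so the tumor-free field relaxes
    to G everywhere.  D and epsilon are surrogate defaults,
    chosen so nutrient depletion zones form on the scale of a desk-size tumor.
    """

    species: str
    D: float = 100.0                      # voxel^2 / MCS
    epsilon: float = 0.05                 # 1 / MCS
    G_baseline_mM: float = 0.0
    secreted_by_epithelium: bool = True   # ECM + Basal band sites
    secreted_by_stroma: bool = True       # Medium sites

    @property
    def G_baseline(self) -> float:
        """Baseline concentration in fmol/voxel."""
        from .units import mm_to_fmol_per_voxel

        return mm_to_fmol_per_voxel(self.G_baseline_mM)


def _default_fields() -> dict[str, FieldConfig]:
    # Physiological blood values: glucose 5 mM, glutamine 0.65 mM,
    # oxygen 0.056 mM; lactate starts at zero and is fed only by tumor
    # export and necrotic bursts.
    return {
        "glucose": FieldConfig("glucose", D=100.0, epsilon=1.2, G_baseline_mM=5.0),
        "glutamine": FieldConfig("glutamine", D=100.0, epsilon=1.2, G_baseline_mM=0.65),
        "oxygen": FieldConfig("oxygen", D=400.0, epsilon=1.0, G_baseline_mM=0.056),
        "lactate": FieldConfig(
            "lactate", D=100.0, epsilon=0.1, G_baseline_mM=0.0,
            secreted_by_epithelium=False, secreted_by_stroma=False,
        ),
    }


@dataclass
class DecisionParameters:
    """Cell-decision parameters.

    Defaults are the calibrated baseline values; ``atpK``, ``hill_a`` and
    the quiescent threshold multiplier are surrogates not fixed by the
    baseline table, and configurable.
    """

    incvol: float = 15.0          # voxel^2/fmol, growth rate
    decvol: float = 0.025         # target-volume decrement per decision step
    PGrThr: float = 0.09983       # fmol/voxel, PCancer growth threshold
    SGrThr: float = 0.09983       # fmol/voxel, PStem growth threshold
    StressIncrement: float = 0.95
    StressThr: float = 50.5
    N: int = 6                    # neighbor count above which stress accrues
    V_atpmax: float = 0.6
    atpD: float = 0.021           # fmol/voxel, ATP starvation gate
    Total_time: float = 95.0
    Neg_concATP: float = 0.00095
    Pos_conc: float = 0.0628
    V_lacmax: float = 15.393
    LacDeath: float = 1.68        # fmol/voxel, extracellular lactate gate
    Pos_concLac: float = 2.22
    Total_timelac: float = 168.2
    maxdiv: int = 9
    probstem: float = 0.5
    C: float = 6.0                # Health gets multiplied by exp(C)
    # --- surrogate / structural parameters -------------------------------
    atpK: float = 0.021           # Michaelis constant in Eqs 13-14 (surrogate = atpD)
    LacK: float = 0.064           # fmol/voxel (1 mM), fixed by the model
    hill_a: float = 1.0           # Hill exponent of the fitness factor
    quiescent_thr_multiplier: float = 1.5   # necrosis thresholds, Q/stem vs P
    stress_reset_on_relief: bool = True
    V_normal: float = 25.0        # voxels, normal cell volume Vo
    necrotic_core_floor_fraction: float = 0.25
    temp_sd: float = 2.0          # sd of the senescence-limit draw

    def validate(self) -> None:
        if self.atpK <= 0 or self.LacK <= 0:
            raise ValueError("Michaelis constants must be positive")
        if self.hill_a < 1:
            raise ValueError("hill_a must be >= 1")

    @property
    def Pvolmaxmit(self) -> float:
        """Doubling volume triggering mitosis (PCancer)."""
        return 2.0 * self.V_normal

    @property
    def Svolmaxmit(self) -> float:
        """Doubling volume triggering mitosis (PStem); equal to Pvolmaxmit."""
        return 2.0 * self.V_normal


@dataclass
class KnockdownEntry:
    """One scheduled knockdown: reaction name, complete/partial, start day."""

    reaction: str
    mode: str = "complete"        # 'complete' | 'partial'
    day: int = 0

    def validate(self) -> None:
        if self.mode not in ("complete", "partial"):
            raise ValueError(f"unknown knockdown mode {self.mode!r}")
        if self.day < 0:
            raise ValueError("knockdown day must be >= 0")


@dataclass
class MetabolismConfig:
    network: str = "surrogate"    # 'surrogate' or path to an SBML file
    vf_overrides: dict[str, float] = field(default_factory=dict)
    km_overrides: dict[str, float] = field(default_factory=dict)
    knockdowns: list[KnockdownEntry] = field(default_factory=list)
    dt_substep_min: float = 0.5   # RK4 substep, minutes
    partial_mean: float = 0.1     # partial knockdown ~ Normal(0.1, 0.2)*Vf, truncated at 0
    partial_sd: float = 0.2


@dataclass
class GeometryConfig:
    width: int = 400
    height: int = 400
    band_depth: int = 40          # epithelial band thickness, voxels
    epithelial_cell_size: int = 8 # square epithelial cells, voxels per side
    n_initial_cells: int = 9
    scenario: str = "I"           # I..V initial-heterogeneity scenario

    def validate(self) -> None:
        if self.scenario not in ("I", "II", "III", "IV", "V"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if 2 * self.band_depth >= self.height:
            raise ValueError("epithelial bands overlap: band_depth too large")


@dataclass
class ClockConfig:
    minutes_per_mcs: float = 6.0
    decision_interval_mcs: int = 50   # 5 h
    total_mcs: int = 6000             # 25 days

    @property
    def mcs_per_day(self) -> int:
        return int(round(24 * 60 / self.minutes_per_mcs))

    def day(self, mcs: int) -> float:
        return mcs * self.minutes_per_mcs / (24 * 60)


@dataclass
class SimulationParameters:
    """Complete configuration of one run."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    clock: ClockConfig = field(default_factory=ClockConfig)
    energy: EnergyConfig = field(default_factory=EnergyConfig)
    fields: dict[str, FieldConfig] = field(default_factory=_default_fields)
    decisions: DecisionParameters = field(default_factory=DecisionParameters)
    metabolism: MetabolismConfig = field(default_factory=MetabolismConfig)
    field_refresh_cadence: int = 1    # re-solve fields every this many MCS
    record_metabolites: bool = True

    def validate(self) -> None:
        self.energy.validate()
        self.decisions.validate()
        self.geometry.validate()
        for kd in self.metabolism.knockdowns:
            kd.validate()
        if set(self.fields) != set(SPECIES):
            raise ValueError(f"fields must cover exactly {SPECIES}")

    # ------------------------------------------------------------------
    @classmethod
    def default(cls) -> "SimulationParameters":
        p = cls()
        p.validate()
        return p

    @classmethod
    def desk(cls, width: int = 120, total_mcs: int = 2400) -> "SimulationParameters":
        """Scaled-down configuration for interactive / CI use.

        Same physics and baseline parameters, smaller lattice and shorter
        horizon; epithelial band thinned proportionally.
        """
        p = cls()
        p.geometry.width = width
        p.geometry.height = width
        p.geometry.band_depth = max(8, width // 10)
        p.clock.total_mcs = total_mcs
        p.validate()
        return p

    def copy(self) -> "SimulationParameters":
        import copy as _copy

        return _copy.deepcopy(self)

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


# ----------------------------------------------------------------------
# YAML loading


def _update_dataclass(obj: Any, data: dict[str, Any]) -> None:
    names = {f.name for f in dataclasses.fields(obj)}
    for key, val in data.items():
        if key not in names:
            raise KeyError(f"unknown config key {key!r} for {type(obj).__name__}")
        cur = getattr(obj, key)
        if dataclasses.is_dataclass(cur) and isinstance(val, dict):
            _update_dataclass(cur, val)
        elif isinstance(cur, np.ndarray):
            setattr(obj, key, np.asarray(val, dtype=float))
        else:
            setattr(obj, key, val)


def load_config(path: str | None = None, overrides: dict | None = None) -> SimulationParameters:
    """Build :class:`SimulationParameters` from defaults + YAML + overrides.

    The YAML file mirrors the dataclass structure::

        geometry: {width: 120, height: 120}
        energy:   {Tm: 10.0, lambda_chem: 20.0}
        decisions: {atpD: 0.021}
        fields:
          glucose: {D: 100.0, epsilon: 0.05, G_baseline_mM: 5.0}
        metabolism:
          knockdowns:
            - {reaction: OXPHOS, mode: complete, day: 0}
    """
    params = SimulationParameters()
    merged: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            merged.update(yaml.safe_load(fh) or {})
    if overrides:
        merged.update(overrides)

    for section, data in merged.items():
        if section == "fields":
            for sp, spec in data.items():
                if sp not in params.fields:
                    raise KeyError(f"unknown field species {sp!r}")
                _update_dataclass(params.fields[sp], spec)
        elif section == "metabolism":
            kds = data.pop("knockdowns", None)
            _update_dataclass(params.metabolism, data)
            if kds is not None:
                params.metabolism.knockdowns = [KnockdownEntry(**k) for k in kds]
        elif section in ("field_refresh_cadence", "record_metabolites"):
            setattr(params, section, data)
        else:
            _update_dataclass(getattr(params, section), data)
    params.validate()
    return params
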