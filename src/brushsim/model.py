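"""Unit system, physical/algorithmic parameters and validation.

All internal computation is carried out in reduced units: lengths in units
of the bead interaction radius ``rc`` and energies in units of ``kBT``.
The only place physical units (nm, um) appear is at the configuration
boundary and in reporting helpers.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "UnitSystem",
    "InteractionTable",
    "Population",
    "BrushArchitecture",
    "SimulationParameters",
    "TipModel",
    "ParameterError",
    "to_reduced",
    "validate_parameters",
    "chain_counts",
    "normal_architecture",
    "cancer_architecture",
    "load_config",
    "params_from_config",
]

# Physical presets (reduced-unit mapping and cell geometry).
DEFAULT_RC_NM = 0.646
CELL_AREA_NM2 = 20.5
H_MIN_NM = 2.8
H_MAX_NM = 17.5
KAPPA_SOFT = 100.0
KAPPA_STIFF = 2000.0
DEFAULT_TIP_RADIUS_UM = 2.5

#: Default same-species repulsion amplitude (kBT/rc) at bulk density rho*rc^3 = 3.
A_SAME = 25.0
#: Default solvent-brush amplitude, slightly more repulsive than same-species.
A_SOLVENT_BRUSH = 28.0
#: Bulk solvent reduced density the activity is calibrated against.
TARGET_SOLVENT_DENSITY = 3.0
#: Solvent activity holding the a=25 fluid at density 3 (excess chemical
#: potential ~12.1 kBT). Recomputable with gcmc.calibrate_activity.
CALIBRATED_ACTIVITY = 5.822e5


class ParameterError(ValueError):
    """Raised on invalid configuration; carries the full list of failures."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class UnitSystem:
    """Reduced-unit bookkeeping: lengths in rc, energies in kBT."""

    rc_nm: float = DEFAULT_RC_NM
    kBT: float = 1.0
    mass: float = 1.0

    def __post_init__(self):
        if not (self.rc_nm > 0):
            raise ParameterError(["rc_nm must be positive"])

    def to_reduced(self, length_nm: float) -> float:
        """Convert a physical length in nm to reduced units (rc)."""
        if np.any(np.asarray(length_nm) < 0):
            raise ParameterError(["length must be non-negative"])
        return length_nm / self.rc_nm

    def to_nm(self, length_rc: float) -> float:
        """Convert a reduced length (rc) back to nm."""
        return length_rc * self.rc_nm


def to_reduced(length_nm, units: UnitSystem):
    """Convert length in nm to rc. Negative input is a domain error."""
    return units.to_reduced(length_nm)


@dataclass
class InteractionTable:
    """Symmetric conservative repulsion amplitudes, indexed by species.

    Species 0 is the solvent; species ``1..P`` are the brush populations.
    ``a`` is in kBT/rc; the two wall amplitudes act on every species.
    """

    a: np.ndarray
    a_wall_surface: float = A_SAME
    a_wall_tip: float = A_SAME

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)

    @classmethod
    def default(cls, n_populations: int, a_same: float = A_SAME,
                a_solvent_brush: float = A_SOLVENT_BRUSH,
                a_wall_surface: float = A_SAME,
                a_wall_tip: float = A_SAME) -> "InteractionTable":
        """Amplitudes equal within a type; solvent-brush slightly more repulsive."""
        n = n_populations + 1
        a = np.full((n, n), a_same, dtype=float)
        a[0, 1:] = a_solvent_brush
        a[1:, 0] = a_solvent_brush
        return cls(a=a, a_wall_surface=a_wall_surface, a_wall_tip=a_wall_tip)

    def check(self) -> list[str]:
        errors = []
        a = self.a
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            errors.append("interaction matrix must be square")
            return errors
        if not np.allclose(a, a.T):
            errors.append("interaction matrix must be symmetric")
        if np.any(a < 0):
            errors.append("repulsion amplitudes must be non-negative")
        if a.shape[0] > 1 and np.any(a[0, 1:] < a[0, 0]):
            errors.append("solvent-brush amplitude must be >= solvent-solvent amplitude")
        if self.a_wall_surface < 0 or self.a_wall_tip < 0:
            errors.append("wall amplitudes must be non-negative")
        return errors


@dataclass(frozen=True)
class Population:
    """One brush population: chain length, grafting density and bond stiffness."""

    N: int
    Gamma_nm2: float
    kappa: float


@dataclass
class BrushArchitecture:
    """The set of brush populations on the surface plus graft mobility."""

    populations: list[Population]
    mobility: str = "liquid"  # "liquid" (grafts diffuse in xy) | "solid" (frozen)

    def check(self) -> list[str]:
        errors = []
        if self.mobility not in ("liquid", "solid"):
            errors.append(f"mobility must be 'liquid' or 'solid', got {self.mobility!r}")
        if not self.populations:
            errors.append("architecture must define at least one brush population")
        for i, p in enumerate(self.populations):
            if p.N < 1:
                errors.append(f"population {i}: chain length N must be >= 1")
            if not (p.Gamma_nm2 > 0):
                errors.append(f"population {i}: grafting density must be positive")
            if not (p.kappa > 0):
                errors.append(f"population {i}: spring constant must be positive")
        return errors

    @property
    def n_populations(self) -> int:
        return len(self.populations)


def normal_architecture(mobility: str = "liquid") -> BrushArchitecture:
    """Uniform brush preset: one population, N=27, Gamma=0.78 nm^-2, kappa=100."""
    return BrushArchitecture(
        populations=[Population(N=27, Gamma_nm2=0.78, kappa=KAPPA_SOFT)],
        mobility=mobility,
    )


def cancer_architecture(stiffness: str = "soft",
                        mobility: str = "liquid") -> BrushArchitecture:
    """Three-population preset: N = 5/30/42, Gamma = 1.76/0.49/0.20 nm^-2.

    ``stiffness`` selects the bond spring constant on every chain:
    100 kBT/rc^2 ("soft") or 2000 kBT/rc^2 ("stiff"), a ratio of 20.
    """
    if stiffness not in ("soft", "stiff"):
        raise ParameterError([f"stiffness must be 'soft' or 'stiff', got {stiffness!r}"])
    kappa = KAPPA_SOFT if stiffness == "soft" else KAPPA_STIFF
    return BrushArchitecture(
        populations=[
            Population(N=5, Gamma_nm2=1.76, kappa=kappa),
            Population(N=30, Gamma_nm2=0.49, kappa=kappa),
            Population(N=42, Gamma_nm2=0.20, kappa=kappa),
        ],
        mobility=mobility,
    )


@dataclass(frozen=True)
class TipModel:
    """Probe metadata. The simulated tip is a planar wall (the probe's contact
    area is much larger than the box); the nominal radius only enters reporting
    through the Derjaguin transform F/R."""

    R_um: float = DEFAULT_TIP_RADIUS_UM
    geometry: str = "planar-wall"

    def __post_init__(self):
        if not (self.R_um > 0):
            raise ParameterError(["tip radius must be positive"])


@dataclass
class SimulationParameters:
    """Everything needed to reproduce one run, in reduced units."""

    units: UnitSystem = field(default_factory=UnitSystem)
    interactions: InteractionTable | None = None
    architecture: BrushArchitecture = field(default_factory=normal_architecture)
    tip: TipModel = field(default_factory=TipModel)
    box_xy: tuple[float, float] = None  # lateral box lengths in rc
    h: float = None                     # wall separation in rc
    activity: float = CALIBRATED_ACTIVITY  # solvent activity z
    target_density: float = TARGET_SOLVENT_DENSITY
    max_displacement: float = 0.25      # rc; auto-tuned during equilibration
    n_equilibration: int = 300
    n_production: int = 600
    sample_interval: int = 3
    seed: int = 0
    bond_rest_length: float = 0.0       # r0 in rc
    bin_width: float = 0.2              # density-profile bin width in rc
    exclude_bonded_pairs: bool = False

    def __post_init__(self):
        side = math.sqrt(CELL_AREA_NM2) / self.units.rc_nm
        if self.box_xy is None:
            self.box_xy = (side, side)
        else:
            self.box_xy = tuple(float(v) for v in self.box_xy)
        if self.h is None:
            self.h = self.units.to_reduced(H_MAX_NM)
        if self.interactions is None:
            self.interactions = InteractionTable.default(self.architecture.n_populations)

    @property
    def area_rc2(self) -> float:
        return self.box_xy[0] * self.box_xy[1]

    @property
    def area_nm2(self) -> float:
        return self.area_rc2 * self.units.rc_nm ** 2

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "units": dataclasses.asdict(self.units),
            "interactions": {
                "a": self.interactions.a.tolist(),
                "a_wall_surface": self.interactions.a_wall_surface,
                "a_wall_tip": self.interactions.a_wall_tip,
            },
            "architecture": {
                "populations": [dataclasses.asdict(p) for p in self.architecture.populations],
                "mobility": self.architecture.mobility,
            },
            "tip": dataclasses.asdict(self.tip),
            "box_xy": list(self.box_xy),
            "h": self.h,
            "activity": self.activity,
            "target_density": self.target_density,
            "max_displacement": self.max_displacement,
            "n_equilibration": self.n_equilibration,
            "n_production": self.n_production,
            "sample_interval": self.sample_interval,
            "seed": self.seed,
            "bond_rest_length": self.bond_rest_length,
            "bin_width": self.bin_width,
            "exclude_bonded_pairs": self.exclude_bonded_pairs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParameters":
        d = dict(d)
        units = UnitSystem(**d.pop("units"))
        it = d.pop("interactions")
        interactions = InteractionTable(a=np.asarray(it["a"], dtype=float),
                                        a_wall_surface=it["a_wall_surface"],
                                        a_wall_tip=it["a_wall_tip"])
        arch = d.pop("architecture")
        architecture = BrushArchitecture(
            populations=[Population(**p) for p in arch["populations"]],
            mobility=arch["mobility"],
        )
        tip = TipModel(**d.pop("tip"))
        d["box_xy"] = tuple(d["box_xy"])
        return cls(units=units, interactions=interactions,
                   architecture=architecture, tip=tip, **d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "SimulationParameters":
        return cls.from_dict(json.loads(s))

    def replace(self, **kw) -> "SimulationParameters":
        return dataclasses.replace(self, **kw)


def chain_counts(architecture: BrushArchitecture, area_nm2: float) -> list[int]:
    """Number of grafted chains per population: round(Gamma_i * A), each >= 1."""
    if not (area_nm2 > 0):
        raise ParameterError(["cell area must be positive"])
    counts = []
    errors = []
    for i, p in enumerate(architecture.populations):
        c = int(round(p.Gamma_nm2 * area_nm2))
        if c < 1:
            errors.append(
                f"population {i}: Gamma*A = {p.Gamma_nm2 * area_nm2:.3g} rounds to 0 chains"
            )
        counts.append(c)
    if errors:
        raise ParameterError(errors)
    return counts


def validate_parameters(params: SimulationParameters) -> SimulationParameters:
    """Check every configuration invariant; raise :class:`ParameterError` with
    the complete list of failures, or return the parameters unchanged."""
    errors: list[str] = []
    errors += params.interactions.check()
    errors += params.architecture.check()
    if params.interactions.a.shape[0] != params.architecture.n_populations + 1:
        errors.append(
            "interaction matrix size must be n_populations + 1 "
            f"(got {params.interactions.a.shape[0]}, "
            f"need {params.architecture.n_populations + 1})"
        )
    if not (params.box_xy[0] > 0 and params.box_xy[1] > 0):
        errors.append("box_xy must be positive")
    if not (params.h > 0):
        errors.append("wall separation h must be positive")
    if not (params.max_displacement > 0):
        errors.append("max_displacement must be positive")
    if params.activity < 0:
        errors.append("activity must be non-negative")
    if params.n_equilibration < 0 or params.n_production < 0:
        errors.append("sweep counts must be non-negative")
    if params.sample_interval < 1:
        errors.append("sample_interval must be >= 1")
    if not (params.bin_width > 0):
        errors.append("bin_width must be positive")
    if params.bond_rest_length < 0:
        errors.append("bond_rest_length must be non-negative")
    if not params.architecture.check():
        try:
            chain_counts(params.architecture, params.area_nm2)
        except ParameterError as e:
            errors += e.errors
    if errors:
        raise ParameterError(errors)
    return params


def verify_stiffness_pair(soft: BrushArchitecture, stiff: BrushArchitecture,
                          ratio: float = KAPPA_STIFF / KAPPA_SOFT) -> float:
    """Check that two architectures form a matched soft/stiff pair
    (same N and Gamma per population, kappa_stiff = ratio * kappa_soft).
    Returns the common stiffness ratio."""
    errors = []
    if len(soft.populations) != len(stiff.populations):
        errors.append("soft and stiff architectures must have the same populations")
    else:
        for i, (ps, pt) in enumerate(zip(soft.populations, stiff.populations)):
            if ps.N != pt.N or not math.isclose(ps.Gamma_nm2, pt.Gamma_nm2):
                errors.append(f"population {i}: N/Gamma mismatch between soft and stiff")
            if not math.isclose(pt.kappa, ratio * ps.kappa):
                errors.append(
                    f"population {i}: kappa_stiff must be {ratio:g} x kappa_soft "
                    f"(got {pt.kappa:g} vs {ps.kappa:g})"
                )
    if errors:
        raise ParameterError(errors)
    return ratio


# -- configuration files --------------------------------------------------

_LENGTH_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*(nm|rc)\s*$")


def _parse_length(value, units: UnitSystem) -> float:
    """Accept lengths as a number (rc), '2.8 nm' / '4.3 rc' strings, or
    {'value': x, 'unit': 'nm'|'rc'} mappings; return rc."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        m = _LENGTH_RE.match(value)
        if not m:
            raise ParameterError([f"cannot parse length {value!r}"])
        v, unit = float(m.group(1)), m.group(2)
    elif isinstance(value, dict):
        v, unit = float(value["value"]), value.get("unit", "rc")
    else:
        raise ParameterError([f"cannot parse length {value!r}"])
    if unit == "nm":
        return units.to_reduced(v)
    return v


def load_config(path) -> dict:
    """Read a TOML or JSON experiment configuration."""
    text = open(path, "rb").read()
    if str(path).endswith(".json"):
        return json.loads(text)
    import tomllib
    return tomllib.loads(text.decode())


def params_from_config(cfg: dict) -> SimulationParameters:
    """Build validated SimulationParameters from a configuration mapping.

    Recognized keys mirror the SimulationParameters fields; ``preset``
    ("normal" | "cancer"), ``stiffness`` and ``mobility`` select the
    architecture; lengths carry an explicit unit tag ('nm' or 'rc').
    """
    cfg = dict(cfg)
    units = UnitSystem(rc_nm=float(cfg.pop("rc_nm", DEFAULT_RC_NM)))
    preset = cfg.pop("preset", "normal")
    mobility = cfg.pop("mobility", "liquid")
    stiffness = cfg.pop("stiffness", "soft")
    if preset == "normal":
        arch = normal_architecture(mobility=mobility)
    elif preset == "cancer":
        arch = cancer_architecture(stiffness=stiffness, mobility=mobility)
    else:
        raise ParameterError([f"unknown preset {preset!r}"])

    kw: dict = {"units": units, "architecture": arch}
    if "h" in cfg:
        kw["h"] = _parse_length(cfg.pop("h"), units)
    if "box_xy" in cfg:
        kw["box_xy"] = tuple(_parse_length(v, units) for v in cfg.pop("box_xy"))
    if "interactions" in cfg:
        it = cfg.pop("interactions")
        kw["interactions"] = InteractionTable(
            a=np.asarray(it["a"], dtype=float),
            a_wall_surface=float(it.get("a_wall_surface", A_SAME)),
            a_wall_tip=float(it.get("a_wall_tip", A_SAME)),
        )
    if "tip_radius_um" in cfg:
        kw["tip"] = TipModel(R_um=float(cfg.pop("tip_radius_um")))
    for key in ("activity", "target_density", "max_displacement",
                "bond_rest_length", "bin_width"):
        if key in cfg:
            kw[key] = float(cfg.pop(key))
    for key in ("n_equilibration", "n_production", "sample_interval", "seed"):
        if key in cfg:
            kw[key] = int(cfg.pop(key))
    if "exclude_bonded_pairs" in cfg:
        kw["exclude_bonded_pairs"] = bool(cfg.pop("exclude_bonded_pairs"))
    cfg.pop("h_grid", None)
    cfg.pop("seeds", None)
    cfg.pop("n_h", None)
    if cfg:
        raise ParameterError([f"unknown configuration keys: {sorted(cfg)}"])
    return validate_parameters(SimulationParameters(**kw))
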