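"""Model parameters: spring specifications, cross-bridge assemblies, and
thermodynamic / kinetic parameter sets.

The three cross-bridge models are assemblies of linearly elastic springs:

``1sXB``
    the classic single extensional spring parallel to the thick filament;
``2sXB``
    a torsional spring at the thick-filament anchor plus an extensional
    lever arm (base angle and base-to-tip length);
``4sXB``
    a chain of four springs mirroring myosin structure: a torsional spring
    where S2 leaves the thick-filament backbone, the extensional S2 rod, the
    torsional converter at the S2/light-chain-domain junction, and the
    extensional light-chain domain (LCD).

The power stroke is represented purely as a switch in spring *rest* values
(no spring is added or removed): the converter rest angle drops from 125 deg
to 70 deg for the 4sXB, and the 2sXB's base angle / arm length switch so its
head tracks the 4sXB head.  Pre-power-stroke rest values apply in kinetic
states 1 and 2, post-power-stroke values in state 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import yaml

SpringKind = Literal["torsional", "extensional"]
StateId = Literal[1, 2, 3]

#: Boltzmann constant times temperature, pN nm (T ~ 298 K).
DEFAULT_KT = 4.11

#: Lineage nucleotide concentrations (molar) for the ATP free-energy budget.
DEFAULT_ATP, DEFAULT_ADP, DEFAULT_PI = 5e-3, 30e-6, 3e-3


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class SpringSpec:
    """One linearly elastic element of a cross-bridge.

    Parameters
    ----------
    kind
        ``"torsional"`` (angular, watch-like) or ``"extensional"`` (Hookean).
    rest_pre, rest_post
        Rest value before / after the power stroke.  Radians for torsional
        springs, nm for extensional ones.
    stiffness
        pN nm/rad for torsional springs, pN/nm for extensional ones.
    name
        Short label, e.g. ``"converter"``.
    """

    kind: SpringKind
    rest_pre: float
    rest_post: float
    stiffness: float
    name: str = ""

    def __post_init__(self) -> None:
        _require(self.kind in ("torsional", "extensional"),
                 f"unknown spring kind {self.kind!r}")
        _require(self.stiffness > 0, "stiffness must be positive")
        if self.kind == "torsional":
            for r in (self.rest_pre, self.rest_post):
                _require(0 < r < math.pi,
                         "torsional rest angle must lie in (0, pi) rad")
        else:
            # The 1sXB post-stroke rest length is exactly 0, so allow >= 0.
            _require(self.rest_pre >= 0 and self.rest_post >= 0,
                     "extensional rest length must be non-negative")

    def rest(self, state: StateId) -> float:
        """Rest value in kinetic state 1, 2 (pre-stroke) or 3 (post-stroke)."""
        _require(state in (1, 2, 3), f"invalid state {state}")
        return self.rest_post if state == 3 else self.rest_pre


@dataclass(frozen=True)
class CrossBridgeModel:
    """A named, ordered assembly of springs with its solving contract.

    Use the factory functions :func:`one_spring`, :func:`two_spring` and
    :func:`four_spring` to build the standard parameterisations.
    """

    name: Literal["1sXB", "2sXB", "4sXB"]
    springs: tuple[SpringSpec, ...]

    _COUNTS = {"1sXB": 1, "2sXB": 2, "4sXB": 4}

    def __post_init__(self) -> None:
        _require(self.name in self._COUNTS, f"unknown model {self.name!r}")
        _require(len(self.springs) == self._COUNTS[self.name],
                 f"{self.name} needs {self._COUNTS[self.name]} springs, "
                 f"got {len(self.springs)}")

    def spring(self, name: str) -> SpringSpec:
        for s in self.springs:
            if s.name == name:
                return s
        raise KeyError(name)


def four_spring() -> CrossBridgeModel:
    """The 4sXB with its standard parameter set.

    Rest values and stiffnesses follow the structural literature: the S2/rod
    junction angle rests at 40 deg (100 pN nm/rad) and does not change with
    the power stroke; S2 is a 10.5 nm rod (10 pN/nm); the converter rest
    angle swings from 125 deg to 70 deg with the stroke (40 pN nm/rad); the
    LCD lever is 9.6 nm long (5 pN/nm).  Converter angles are measured
    between the LCD and the thick-filament axis pointing away from the
    binding site, so the pre-stroke head sits forward of the base and the
    stroke drags the thin filament toward smaller axial offsets.
    """
    d = math.radians
    return CrossBridgeModel("4sXB", (
        SpringSpec("torsional", d(40.0), d(40.0), 100.0, name="base"),
        SpringSpec("extensional", 10.5, 10.5, 10.0, name="s2"),
        SpringSpec("torsional", d(125.0), d(70.0), 40.0, name="converter"),
        SpringSpec("extensional", 9.6, 9.6, 5.0, name="lcd"),
    ))


def _four_spring_rest_tips() -> dict[StateId, tuple[float, float]]:
    """Rest tip (axial, radial) of the 4sXB per state, closed form."""
    m = four_spring()
    base, s2, conv, lcd = m.springs
    tips: dict[StateId, tuple[float, float]] = {}
    for state in (2, 3):
        th1, l2 = base.rest(state), s2.rest(state)
        th3, l4 = conv.rest(state), lcd.rest(state)
        cx, cy = l2 * math.cos(th1), l2 * math.sin(th1)
        # LCD absolute angle from the +axial direction is pi - converter angle
        tips[state] = (cx + l4 * math.cos(math.pi - th3),
                       cy + l4 * math.sin(math.pi - th3))
    return tips


def two_spring() -> CrossBridgeModel:
    """The 2sXB, rest values derived so its head co-locates with the 4sXB's.

    The base-angle and arm-length rest values are computed from the 4sXB
    rest tip in each state (they evaluate to 47.16 deg / 19.93 nm before the
    stroke and 73.20 deg / 16.47 nm after, i.e. the rounded tabulated values
    47 / 20 and 73 / 16).  Stiffnesses: 40 pN nm/rad, 2 pN/nm.
    """
    tips = _four_spring_rest_tips()
    (x2, y2), (x3, y3) = tips[2], tips[3]
    return CrossBridgeModel("2sXB", (
        SpringSpec("torsional", math.atan2(y2, x2), math.atan2(y3, x3),
                   40.0, name="base"),
        SpringSpec("extensional", math.hypot(x2, y2), math.hypot(x3, y3),
                   2.0, name="arm"),
    ))


def one_spring() -> CrossBridgeModel:
    """The single-spring reference: 5 pN/nm, rest 5 nm pre / 0 nm post."""
    return CrossBridgeModel("1sXB", (
        SpringSpec("extensional", 5.0, 0.0, 5.0, name="xb"),
    ))


_FACTORIES = {"1sXB": one_spring, "2sXB": two_spring, "4sXB": four_spring}


def get_model(name: str) -> CrossBridgeModel:
    """Build a standard model by name (``"1sXB"``, ``"2sXB"``, ``"4sXB"``)."""
    try:
        return _FACTORIES[name]()
    except KeyError:
        raise ValueError(f"unknown model {name!r}") from None


def atp_free_energy_kt(atp: float = DEFAULT_ATP, adp: float = DEFAULT_ADP,
                       pi: float = DEFAULT_PI, dg0_kt: float = 13.0) -> float:
    """Free energy liberated per ATP cycle, in kT units.

    ``dG = dG0 + kT ln([ATP] / ([ADP][Pi]))`` with the standard free energy
    of hydrolysis ``dG0 = 13 kT`` and concentrations in molar.  The defaults
    give 23.93 kT (~98 pN nm).
    """
    _require(min(atp, adp, pi) > 0, "concentrations must be positive")
    return dg0_kt + math.log(atp / (adp * pi))


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic constants shared across the energetics and kinetics.

    Attributes
    ----------
    dg_atp_total : float
        Free energy liberated per ATP cycle, kT units (default 23.93 from
        the standard free energy plus concentration terms).
    eff_state2, eff_state3 : float
        Fraction of the ATP budget available in the weakly bound (28%) and
        strongly bound (68%) states.
    kt : float
        Boltzmann constant times temperature, pN nm.
    timestep : float
        Kinetic time step, s.
    """

    dg_atp_total: float = field(default_factory=atp_free_energy_kt)
    eff_state2: float = 0.28
    eff_state3: float = 0.68
    kt: float = DEFAULT_KT
    timestep: float = 1e-3

    def __post_init__(self) -> None:
        _require(0 < self.eff_state2 < self.eff_state3 < 1,
                 "efficiencies must satisfy 0 < eff2 < eff3 < 1")
        _require(self.kt > 0, "kT must be positive")
        _require(self.timestep > 0, "timestep must be positive")

    def baseline(self, state: StateId) -> float:
        """ATP/efficiency term of the state free energy, pN nm (<= 0)."""
        eff = {1: 0.0, 2: self.eff_state2, 3: self.eff_state3}[state]
        return -eff * self.dg_atp_total * self.kt


#: Binding-probability scale factors chosen so attachment rates agree
#: between the multi-spring models (more thermally forced springs spread
#: the 4sXB's diffusion cloud, so it needs the smaller capture scale).
DEFAULT_TAU = {"1sXB": 12.0, "2sXB": 72.0, "4sXB": 12.0}


@dataclass(frozen=True)
class BindingParams:
    """Monte-Carlo binding parameters (diffuse-then-bind step)."""

    tau: float
    ensemble_n: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.tau > 0, "tau must be positive")
        _require(self.ensemble_n >= 1, "ensemble_n must be >= 1")

    @classmethod
    def for_model(cls, model: CrossBridgeModel | str, **kw) -> "BindingParams":
        name = model if isinstance(model, str) else model.name
        return cls(tau=DEFAULT_TAU[name], **kw)


@dataclass(frozen=True)
class KineticParams:
    """Constants of the strain-dependent rate laws.

    ``r23 = (r23_max / 2) (1 + tanh(r23_shift + r23_slope (G2 - G3)/kT))``
    keeps the single-spring lineage's sigmoidal power-stroke law, with the
    axial strain replaced by the full two-dimensional free-energy drop.

    ``r31 = r31_rest exp(r31_alpha U3 / kT)`` with ``U3`` the post-stroke
    elastic strain energy at the binding site.  ``r31_rest`` is anchored to
    the slowest observed detachment at rest lattice spacing (20 /s) and
    ``r31_alpha`` is calibrated in closed form from the 260 /s detachment
    floor at d10 = 38 nm (see :func:`xbmech.kinetics.calibrate_detachment`).
    """

    r23_max: float = 1200.0
    r23_shift: float = 4.0
    r23_slope: float = 0.4
    r31_rest: float = 20.0
    r31_alpha: float = 2.8088
    exp_clamp: float = 50.0

    def __post_init__(self) -> None:
        _require(self.r23_max > 0 and self.r31_rest > 0, "rates must be > 0")
        _require(self.exp_clamp > 0, "exp_clamp must be positive")


# ---------------------------------------------------------------------------
# Parameter-file IO (structured YAML mirroring the tabulated parameter set)

def model_to_dict(model: CrossBridgeModel) -> dict:
    return {
        "name": model.name,
        "springs": [
            {"name": s.name, "kind": s.kind,
             "rest_pre": (math.degrees(s.rest_pre)
                          if s.kind == "torsional" else s.rest_pre),
             "rest_post": (math.degrees(s.rest_post)
                           if s.kind == "torsional" else s.rest_post),
             "stiffness": s.stiffness,
             "units": ("deg, pN*nm/rad" if s.kind == "torsional"
                       else "nm, pN/nm")}
            for s in model.springs
        ],
    }


def model_from_dict(d: dict) -> CrossBridgeModel:
    springs = tuple(
        SpringSpec(
            kind=s["kind"],
            rest_pre=(math.radians(s["rest_pre"])
                      if s["kind"] == "torsional" else s["rest_pre"]),
            rest_post=(math.radians(s["rest_post"])
                       if s["kind"] == "torsional" else s["rest_post"]),
            stiffness=s["stiffness"],
            name=s.get("name", ""),
        )
        for s in d["springs"]
    )
    return CrossBridgeModel(d["name"], springs)


def default_config() -> dict:
    """Default parameter file content: all three models plus constants."""
    return {
        "models": [model_to_dict(one_spring()), model_to_dict(two_spring()),
                   model_to_dict(four_spring())],
        "thermo": {"dg_atp_total_kt": atp_free_energy_kt(),
                   "eff_state2": 0.28, "eff_state3": 0.68,
                   "kt_pn_nm": DEFAULT_KT, "timestep_s": 1e-3},
        "binding": {"tau": dict(DEFAULT_TAU), "ensemble_n": 10_000},
        "lattice": {"rest_d10_nm": 34.0, "d10_window_nm": [30.0, 38.0]},
    }


def write_config(path: str | Path, config: dict | None = None) -> Path:
    """Emit the default parameter file (the shipped fixture generator)."""
    path = Path(path)
    path.write_text(yaml.safe_dump(config or default_config(),
                                   sort_keys=False))
    return path


def read_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    _require(isinstance(cfg, dict) and "models" in cfg,
             "parameter file must be a mapping with a 'models' list")
    return cfg


def models_from_config(cfg: dict) -> dict[str, CrossBridgeModel]:
    return {d["name"]: model_from_dict(d) for d in cfg["models"]}


def thermo_from_config(cfg: dict) -> ThermoParams:
    t = cfg.get("thermo", {})
    return ThermoParams(
        dg_atp_total=t.get("dg_atp_total_kt", atp_free_energy_kt()),
        eff_state2=t.get("eff_state2", 0.28),
        eff_state3=t.get("eff_state3", 0.68),
        kt=t.get("kt_pn_nm", DEFAULT_KT),
        timestep=t.get("timestep_s", 1e-3),
    )


__all__ = [
    "SpringSpec", "CrossBridgeModel", "ThermoParams", "BindingParams",
    "KineticParams", "StateId", "one_spring", "two_spring", "four_spring",
    "get_model", "atp_free_energy_kt", "DEFAULT_KT", "DEFAULT_TAU",
    "default_config", "write_config", "read_config", "models_from_config",
    "thermo_from_config", "model_to_dict", "model_from_dict", "replace",
]
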