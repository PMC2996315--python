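"""State free energies and force generation.

A bound cross-bridge in kinetic state *i* at head position *t* has

    ``G_i(t) = -eff_i * dG_ATP + U_i(t)``

where ``dG_ATP`` is the free energy liberated per ATP cycle, ``eff_i`` the
fraction available in that state (28% weakly bound, 68% strongly bound) and
``U_i`` the total elastic strain energy of the springs with the state's rest
values (converter relaxed for the 4sXB).  The unbound state supports no
strain and is the zero reference at every axial offset and lattice spacing.

The reaction force holding the head at a position is the negative gradient
of the strain energy with respect to the head position, split into an axial
component (along the filaments) and a radial one (positive = expansive,
pushing the filaments apart).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import minimize_scalar

from . import geometry, lattice
from .geometry import TipPosition
from .params import CrossBridgeModel, StateId, ThermoParams

#: Default axial search window (nm) for energy minima, spanning the
#: landscape range studied.
AXIAL_WINDOW = (-25.0, 25.0)


@dataclass(frozen=True)
class StateFreeEnergy:
    """Free energy of a cross-bridge state at one head position."""

    state: StateId
    value: float  # pN nm
    tip: TipPosition
    d10: float

    def in_kt(self, thermo: ThermoParams) -> float:
        return self.value / thermo.kt


@dataclass(frozen=True)
class ForceVector:
    """Reaction force (pN) holding the head in place.

    ``axial`` resists further axial displacement; ``radial`` is positive
    when expansive (the cross-bridge pushes the thin filament away).
    """

    axial: float
    radial: float

    def __iter__(self):
        yield self.axial
        yield self.radial


def site_tip(model: CrossBridgeModel, axial: float, d10: float,
             correction: float | None = None) -> TipPosition:
    """Head position with the tip on the binding plane of a given d10."""
    if correction is None:
        correction = lattice.correction_factor(model)
    return TipPosition(axial, lattice.ssls_from_d10(d10, correction))


def free_energy(model: CrossBridgeModel, state: StateId, tip: TipPosition,
                d10: float, thermo: ThermoParams) -> StateFreeEnergy:
    """State free energy (pN nm) at a head position.

    State 1 is identically zero; bound states add the strain energy of the
    state's geometry to the (negative) efficiency-scaled ATP term.
    """
    if state == 1:
        return StateFreeEnergy(1, 0.0, tip, d10)
    u = geometry.elastic_energy(model, tip, state)
    return StateFreeEnergy(state, thermo.baseline(state) + u, tip, d10)


def free_energy_at(model: CrossBridgeModel, state: StateId, axial: float,
                   d10: float, thermo: ThermoParams,
                   correction: float | None = None) -> StateFreeEnergy:
    """Free energy with the tip on the binding plane at ``axial`` offset."""
    return free_energy(model, state,
                       site_tip(model, axial, d10, correction), d10, thermo)


def reaction_force(model: CrossBridgeModel, state: StateId, tip: TipPosition,
                   d10: float = float("nan")) -> ForceVector:
    """Reaction force at a head position for a bound state (2 or 3).

    For the 4sXB the converter is relaxed first; by the envelope property
    the gradient of the optimised energy equals the partial gradient with
    the converter frozen at its optimum.
    """
    if state == 1:
        raise ValueError("the unbound state supports no strain")
    g = geometry.elastic_gradient(model, tip, state)
    return ForceVector(-float(g[0]), -float(g[1]))


def argmin_energy_offset(model: CrossBridgeModel, state: StateId, d10: float,
                         correction: float | None = None,
                         window: tuple[float, float] = AXIAL_WINDOW,
                         coarse: float = 0.5, xatol: float = 1e-4) -> float:
    """Axial offset (nm) minimising the state's energy on the binding plane.

    Grid pre-bracketing at ``coarse`` resolution followed by bounded scalar
    minimisation to ``xatol``.
    """
    if correction is None:
        correction = lattice.correction_factor(model)
    y = lattice.ssls_from_d10(d10, correction)

    def u(x: float) -> float:
        return geometry.elastic_energy(model, TipPosition(x, y), state)

    lo, hi = window
    n = max(int(round((hi - lo) / coarse)), 2)
    xs = [lo + i * (hi - lo) / n for i in range(n + 1)]
    es = [u(x) for x in xs]
    i = es.index(min(es))
    blo, bhi = xs[max(i - 1, 0)], xs[min(i + 1, n)]
    res = minimize_scalar(u, bounds=(blo, bhi), method="bounded",
                          options={"xatol": xatol})
    return float(res.x)


def step_size(model: CrossBridgeModel, d10: float,
              correction: float | None = None,
              window: tuple[float, float] = AXIAL_WINDOW) -> float:
    """Power-stroke step size (nm) at a lattice spacing.

    The axial distance between the pre- and post-stroke energy-minimising
    head positions on the binding plane; positive for a forward stroke
    (the pre-stroke minimum sits at the larger axial offset).
    """
    if model.name == "1sXB":
        s = model.springs[0]
        return s.rest_pre - s.rest_post
    a2 = argmin_energy_offset(model, 2, d10, correction, window)
    a3 = argmin_energy_offset(model, 3, d10, correction, window)
    return a2 - a3


def max_step_size(model: CrossBridgeModel,
                  d10_window: tuple[float, float] = (30.0, 38.0),
                  resolution: float = 0.5,
                  refine: float = 0.05) -> tuple[float, float]:
    """Maximum step size over a d10 window and where it occurs.

    Scans the window at ``resolution`` nm in d10, then refines around the
    best grid point at ``refine`` nm.  Returns ``(step_nm, d10_nm)``.
    """
    corr = (lattice.correction_factor(model)
            if model.name != "1sXB" else None)
    lo, hi = d10_window
    n = int(round((hi - lo) / resolution))
    ds = [lo + i * (hi - lo) / n for i in range(n + 1)]
    steps = [step_size(model, d, corr) for d in ds]
    i = steps.index(max(steps))
    best_d, best_s = ds[i], steps[i]
    flo = max(lo, best_d - resolution)
    fhi = min(hi, best_d + resolution)
    d = flo
    while d <= fhi + 1e-9:
        if abs(d - best_d) > 1e-9:
            s = step_size(model, d, corr)
            if s > best_s:
                best_s, best_d = s, d
        d += refine
    return best_s, best_d


__all__ = ["StateFreeEnergy", "ForceVector", "free_energy", "free_energy_at",
           "reaction_force", "argmin_energy_offset", "step_size", "site_tip",
           "max_step_size", "AXIAL_WINDOW"]
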