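"""Spring geometry: solving spring lengths/angles for a given head position.

Coordinate frame: the thick-filament long axis is x (axial, positive toward
the binding site), the radial separation is y.  The cross-bridge attaches to
the thick filament at the origin; binding sites live on the plane
``y = ssLS`` (surface-to-surface lattice spacing).

For the 2sXB both spring values follow in closed form from the tip position
(arm length = base-to-tip distance, base angle = elevation of that vector).
The 4sXB has an interior free point - the converter, where S2 meets the
light-chain domain - whose position cannot be written in closed form; it is
found by minimising the total elastic energy, mirroring how the real lever
arm relaxes for a fixed head position.  Once the converter is placed, the
remaining angles and lengths again follow analytically:

* base angle  ``theta1 = atan2(yc, xc)``  (S2 elevation),
* S2 length   ``L2 = |c|``,
* converter angle ``theta3 = atan2(yt - yc, xc - xt)`` - the angle between
  the LCD and the thick-filament axis, measured from the axis direction
  pointing away from the binding site (so the 125 deg pre-stroke rest puts
  the head forward of the base),
* LCD length  ``L4 = |t - c|``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .params import CrossBridgeModel, SpringSpec, StateId

#: Tips closer to the filament surface than this are outside the physical
#: lattice window and are rejected rather than extrapolated.
MIN_RADIAL = 0.5


class SolverError(RuntimeError):
    """4sXB converter optimisation failed; carries the last iterate."""

    def __init__(self, msg: str, last_iterate=None):
        super().__init__(msg)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class TipPosition:
    """Cross-bridge head position: axial offset and radial separation, nm.

    The axial offset is the distance along the filament axis between the
    head and the thick-filament attachment point; the radial coordinate is
    the surface-to-surface thick-thin separation at which the head sits.
    """

    axial: float
    radial: float

    def __post_init__(self) -> None:
        if not self.radial > 0:
            raise ValueError("tip radial separation must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.axial, self.radial])


@dataclass(frozen=True)
class GeometrySolution:
    """Spring values and elastic energy for one head position.

    ``spring_values`` are ordered as the model's springs (radians for
    torsional, nm for extensional).  ``converter_point`` is present only for
    the 4sXB.  ``elastic_energy`` is in pN nm; for the 4sXB it is the
    minimum over converter placements.
    """

    spring_values: tuple[float, ...]
    elastic_energy: float
    converter_point: tuple[float, float] | None = None


def spring_energy(spring: SpringSpec, value: float, state: StateId) -> float:
    """Elastic energy ``(1/2) k (value - rest(state))^2`` in pN nm."""
    if spring.kind == "extensional" and value <= 0 and spring.rest_pre > 0:
        raise ValueError("extensional spring length must be positive")
    dv = value - spring.rest(state)
    return 0.5 * spring.stiffness * dv * dv


def _check_tip(tip: TipPosition) -> None:
    if tip.radial <= MIN_RADIAL:
        raise ValueError(
            f"tip radial {tip.radial} nm is below the physical window "
            f"(> {MIN_RADIAL} nm)")


# ---------------------------------------------------------------------------
# Rest geometry

def rest_converter(model: CrossBridgeModel, state: StateId) -> np.ndarray:
    """Rest position of the 4sXB converter point (axial, radial) nm."""
    if model.name != "4sXB":
        raise ValueError("only the 4sXB has a converter point")
    base, s2 = model.springs[0], model.springs[1]
    th1, l2 = base.rest(state), s2.rest(state)
    return np.array([l2 * math.cos(th1), l2 * math.sin(th1)])


def rest_tip(model: CrossBridgeModel, state: StateId) -> TipPosition:
    """Unstrained head position in the given state."""
    if model.name == "1sXB":
        # one-dimensional: radial coordinate is not part of the model; report
        # a nominal unit separation so the type invariant holds.
        return TipPosition(model.springs[0].rest(state), 1.0)
    if model.name == "2sXB":
        th, arm = (s.rest(state) for s in model.springs)
        return TipPosition(arm * math.cos(th), arm * math.sin(th))
    conv = rest_converter(model, state)
    c3, lcd = model.springs[2], model.springs[3]
    th3, l4 = c3.rest(state), lcd.rest(state)
    return TipPosition(conv[0] + l4 * math.cos(math.pi - th3),
                       conv[1] + l4 * math.sin(math.pi - th3))


# ---------------------------------------------------------------------------
# Forward kinematics

def tip_from_springs(model: CrossBridgeModel,
                     spring_values) -> TipPosition:
    """Head position from spring values (inverse of the solvers).

    For the 4sXB the four values (theta1, L2, theta3, L4) overdetermine
    nothing - the chain is a function - but the map is not injective, so it
    inverts ``solve_4sxb`` only up to the converter redundancy.
    """
    v = tuple(float(x) for x in spring_values)
    if len(v) != len(model.springs):
        raise ValueError("need one value per spring")
    if model.name == "1sXB":
        return TipPosition(v[0], 1.0)
    if model.name == "2sXB":
        th, arm = v
        return TipPosition(arm * math.cos(th), arm * math.sin(th))
    th1, l2, th3, l4 = v
    cx, cy = l2 * math.cos(th1), l2 * math.sin(th1)
    return TipPosition(cx + l4 * math.cos(math.pi - th3),
                       cy + l4 * math.sin(math.pi - th3))


# ---------------------------------------------------------------------------
# Solvers

def solve_1sxb(model: CrossBridgeModel, tip: TipPosition,
               state: StateId) -> GeometrySolution:
    """Single spring spanning base to tip along the axial direction only."""
    spring = model.springs[0]
    x = tip.axial
    dv = x - spring.rest(state)
    return GeometrySolution((x,), 0.5 * spring.stiffness * dv * dv)


def solve_2sxb(model: CrossBridgeModel, tip: TipPosition,
               state: StateId) -> GeometrySolution:
    """Closed-form 2sXB solution: arm length and base angle from the tip."""
    _check_tip(tip)
    x, y = tip.axial, tip.radial
    arm = math.hypot(x, y)
    if arm < 1e-12:
        raise ValueError("tip at the base point: base angle undefined")
    th = math.atan2(y, x)
    base, ext = model.springs
    e = (spring_energy(base, th, state) + spring_energy(ext, arm, state))
    return GeometrySolution((th, arm), e)


def _u4_and_grad(c: np.ndarray, tip: np.ndarray, rests: np.ndarray,
                 ks: np.ndarray) -> tuple[float, np.ndarray]:
    """4sXB elastic energy and its gradient w.r.t. the converter point."""
    xc, yc = c
    xt, yt = tip
    r1r, l2r, r3r, l4r = rests
    k1, k2, k3, k4 = ks
    l2sq = xc * xc + yc * yc
    l2 = math.sqrt(l2sq)
    th1 = math.atan2(yc, xc)
    dx, dy = xt - xc, yt - yc
    l4sq = dx * dx + dy * dy
    l4 = math.sqrt(l4sq)
    th3 = math.atan2(dy, -dx)
    d1, d2, d3, d4 = th1 - r1r, l2 - l2r, th3 - r3r, l4 - l4r
    u = 0.5 * (k1 * d1 * d1 + k2 * d2 * d2 + k3 * d3 * d3 + k4 * d4 * d4)
    # dtheta1/dc = (-yc, xc)/l2^2 ; dl2/dc = (xc, yc)/l2
    # dtheta3/dc = (-dy, -(xc - xt))/l4^2 ; dl4/dc = (-dx, -dy)/l4
    gx = (k1 * d1 * (-yc / l2sq) + k2 * d2 * (xc / l2)
          + k3 * d3 * (-dy / l4sq) + k4 * d4 * (-dx / l4))
    gy = (k1 * d1 * (xc / l2sq) + k2 * d2 * (yc / l2)
          + k3 * d3 * (-(xc - xt) / l4sq) + k4 * d4 * (-dy / l4))
    return u, np.array([gx, gy])


def _model_arrays(model: CrossBridgeModel,
                  state: StateId) -> tuple[np.ndarray, np.ndarray]:
    rests = np.array([s.rest(state) for s in model.springs])
    ks = np.array([s.stiffness for s in model.springs])
    return rests, ks


_JITTER = np.array([[1.0, -1.0], [-1.0, 1.0], [1.5, 1.5],
                    [-1.5, -1.5], [2.5, 0.0]])


def solve_4sxb(model: CrossBridgeModel, tip: TipPosition, state: StateId,
               tol: float = 1e-8, max_iter: int = 500) -> GeometrySolution:
    """Place the converter at the minimum-elastic-energy point for a tip.

    Quasi-Newton descent with the analytic gradient, started from the
    state's rest converter placement; on non-convergence the search restarts
    from jittered guesses before raising :class:`SolverError`.

    ``tol`` is the energy tolerance (pN nm) for convergence.
    """
    _check_tip(tip)
    t = tip.as_array()
    rests, ks = _model_arrays(model, state)
    guess = rest_converter(model, state)
    best = None
    last = guess
    for trial in range(1 + len(_JITTER)):
        g0 = guess if trial == 0 else guess + _JITTER[trial - 1]
        res = minimize(_u4_and_grad, g0, args=(t, rests, ks), jac=True,
                       method="L-BFGS-B",
                       options={"ftol": tol * 1e-4, "gtol": 1e-10,
                                "maxiter": max_iter})
        last = res.x
        if best is None or res.fun < best.fun - 0.0:
            best = res
        if res.success and trial == 0:
            break
    if best is None or not np.isfinite(best.fun):
        raise SolverError("converter optimisation failed", last_iterate=last)
    xc, yc = best.x
    xt, yt = t
    th1 = math.atan2(yc, xc)
    l2 = math.hypot(xc, yc)
    th3 = math.atan2(yt - yc, -(xt - xc))
    l4 = math.hypot(xt - xc, yt - yc)
    return GeometrySolution((th1, l2, th3, l4), float(best.fun),
                            converter_point=(float(xc), float(yc)))


def solve(model: CrossBridgeModel, tip: TipPosition,
          state: StateId, **kw) -> GeometrySolution:
    """Dispatch to the model-appropriate geometry solver."""
    if model.name == "1sXB":
        return solve_1sxb(model, tip, state)
    if model.name == "2sXB":
        return solve_2sxb(model, tip, state)
    return solve_4sxb(model, tip, state, **kw)


def elastic_energy(model: CrossBridgeModel, tip: TipPosition,
                   state: StateId, **kw) -> float:
    """Total elastic strain energy (pN nm) at a head position."""
    return solve(model, tip, state, **kw).elastic_energy


def elastic_gradient(model: CrossBridgeModel, tip: TipPosition,
                     state: StateId) -> np.ndarray:
    """Gradient of the elastic energy w.r.t. the tip position, pN.

    For the 4sXB the converter is first relaxed and then, by the envelope
    property of the minimised energy, only the explicit tip dependence of
    the converter and LCD springs contributes.
    """
    x, y = tip.axial, tip.radial
    if model.name == "1sXB":
        s = model.springs[0]
        return np.array([s.stiffness * (x - s.rest(state)), 0.0])
    if model.name == "2sXB":
        base, ext = model.springs
        rsq = x * x + y * y
        r = math.sqrt(rsq)
        th = math.atan2(y, x)
        dth, dl = th - base.rest(state), r - ext.rest(state)
        kth, kl = base.stiffness, ext.stiffness
        return np.array([kth * dth * (-y / rsq) + kl * dl * (x / r),
                         kth * dth * (x / rsq) + kl * dl * (y / r)])
    sol = solve_4sxb(model, tip, state)
    xc, yc = sol.converter_point
    th3, l4 = sol.spring_values[2], sol.spring_values[3]
    conv, lcd = model.springs[2], model.springs[3]
    dx, dy = x - xc, y - yc
    l4sq = l4 * l4
    d3 = th3 - conv.rest(state)
    d4 = l4 - lcd.rest(state)
    # theta3 = atan2(yt - yc, xc - xt):
    #   d theta3 / d xt = dy / l4^2 ;  d theta3 / d yt = (xc - xt) / l4^2
    gx = conv.stiffness * d3 * (dy / l4sq) + lcd.stiffness * d4 * (dx / l4)
    gy = conv.stiffness * d3 * ((xc - x) / l4sq) \
        + lcd.stiffness * d4 * (dy / l4)
    return np.array([gx, gy])


__all__ = [
    "TipPosition", "GeometrySolution", "SolverError", "MIN_RADIAL",
    "spring_energy", "solve", "solve_1sxb", "solve_2sxb", "solve_4sxb",
    "tip_from_springs", "rest_tip", "rest_converter", "elastic_energy",
    "elastic_gradient",
]
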