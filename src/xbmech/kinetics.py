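"""Strain-dependent three-state kinetics.

The cycle (unbound Myosin-ADP-Pi -> loosely bound pre-stroke -> post-stroke
Actin-Myosin-ADP -> unbound) uses:

* a two-step Monte-Carlo attachment: the unbound head diffuses - each
  spring thermally offset from rest with the Boltzmann statistics of a
  harmonic degree of freedom - then binds with a probability that decays
  exponentially with the squared tip-to-site distance;
* energy-difference-driven power-stroke and detachment rates, functions of
  the state free energies with the tip co-located at the binding site;
* reverse rates fixed by detailed balance against the forward rate and the
  free-energy drop of the forward transition.

All rates are per second; per-time-step probabilities use the 1 ms step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import energetics, geometry, lattice
from .geometry import TipPosition
from .params import (BindingParams, CrossBridgeModel, KineticParams,
                     StateId, ThermoParams)


@dataclass(frozen=True)
class RateConstant:
    """A (possibly estimated) transition rate constant, 1/s."""

    value: float
    transition: tuple[StateId, StateId]
    axial: float = float("nan")
    d10: float = float("nan")
    se: float = 0.0
    n: int = 0

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("rates must be non-negative")

    def __float__(self) -> float:
        return self.value


# ---------------------------------------------------------------------------
# Probability <-> rate conversion

def rate_from_probability(p: float, dt: float, mode: str = "log") -> float:
    """Convert a per-step probability into a rate constant.

    ``"log"`` (default) inverts the exponential waiting time,
    ``r = -ln(1 - p)/dt``; ``"linear"`` uses ``r = p/dt``.
    """
    if not 0 <= p <= 1:
        raise ValueError("probability outside [0, 1]")
    if mode == "linear":
        return p / dt
    if p == 1.0:
        return math.inf
    return -math.log1p(-p) / dt


def probability_from_rate(rate: float, dt: float) -> float:
    """Per-step transition probability ``1 - exp(-rate dt)``."""
    return -math.expm1(-rate * dt)


# ---------------------------------------------------------------------------
# Diffusion + binding (1 -> 2)

def diffuse(model: CrossBridgeModel, rng: np.ndarray | np.random.Generator,
            n: int = 1, kt: float = 4.11) -> np.ndarray:
    """Thermally forced head positions of the unbound cross-bridge.

    Each spring is independently offset from its pre-stroke rest value with
    the Boltzmann statistics of a harmonic degree of freedom - a Gaussian
    offset of variance ``kT/k`` (equipartition) - and the head position is
    recovered by forward kinematics.  Returns an ``(n, 2)`` array of
    (axial, radial) positions; for the 1sXB the radial column is zero.
    """
    rests = np.array([s.rest(2) for s in model.springs])
    sds = np.array([math.sqrt(kt / s.stiffness) for s in model.springs])
    vals = rng.normal(rests, sds, size=(n, len(rests)))
    if model.name == "1sXB":
        return np.column_stack([vals[:, 0], np.zeros(n)])
    if model.name == "2sXB":
        th, arm = vals[:, 0], vals[:, 1]
        return np.column_stack([arm * np.cos(th), arm * np.sin(th)])
    th1, l2, th3, l4 = vals.T
    cx, cy = l2 * np.cos(th1), l2 * np.sin(th1)
    return np.column_stack([cx + l4 * np.cos(np.pi - th3),
                            cy + l4 * np.sin(np.pi - th3)])


def binding_probability(tips: np.ndarray, site: TipPosition | np.ndarray,
                        tau: float, axial_only: bool = False) -> np.ndarray:
    """Per-step binding probability given diffused head positions.

    ``P = min(1, tau exp(-d^2))`` with ``d`` the tip-to-site distance in nm:
    maximal (saturated) within ~``sqrt(ln tau)`` nm of the site and decaying
    exponentially in the squared distance beyond.  ``axial_only`` collapses
    the distance to the axial component (single-spring model).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    s = site.as_array() if isinstance(site, TipPosition) else np.asarray(site)
    t = np.atleast_2d(np.asarray(tips, dtype=float))
    if axial_only:
        d2 = (t[:, 0] - s[0]) ** 2
    else:
        d2 = (t[:, 0] - s[0]) ** 2 + (t[:, 1] - s[1]) ** 2
    return np.minimum(1.0, tau * np.exp(-d2))


def attachment_rate_r12(model: CrossBridgeModel, site: TipPosition,
                        d10: float, params: BindingParams,
                        thermo: ThermoParams | None = None,
                        rng: np.random.Generator | None = None) -> RateConstant:
    """Ensemble Monte-Carlo estimate of the attachment rate constant.

    Runs ``ensemble_n`` independent diffuse-then-bind trials, averages the
    per-step binding probability over the ensemble and converts it to a
    rate at the kinetic time step.  The standard error is propagated
    through the conversion.
    """
    thermo = thermo or ThermoParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    tips = diffuse(model, rng, params.ensemble_n, kt=thermo.kt)
    p = binding_probability(tips, site, params.tau,
                            axial_only=model.name == "1sXB")
    pbar = float(p.mean())
    se_p = float(p.std(ddof=1) / math.sqrt(len(p))) if len(p) > 1 else 0.0
    rate = rate_from_probability(pbar, thermo.timestep)
    se = se_p / ((1.0 - pbar) * thermo.timestep) if pbar < 1 else math.inf
    return RateConstant(rate, (1, 2), site.axial, d10, se=se, n=len(p))


# ---------------------------------------------------------------------------
# Power stroke (2 -> 3) and detachment (3 -> 1)

def powerstroke_rate_r23(model: CrossBridgeModel, site: TipPosition,
                         d10: float, thermo: ThermoParams,
                         kin: KineticParams = KineticParams()) -> RateConstant:
    """Power-stroke rate from the weak-to-strong free-energy drop.

    Sigmoidal in ``(G2 - G3)/kT`` with the tip co-located at the binding
    site (converter relaxed per state for the 4sXB): transitions are fast
    when energetically downhill and shut off smoothly when uphill.
    """
    g2 = energetics.free_energy(model, 2, site, d10, thermo).value
    g3 = energetics.free_energy(model, 3, site, d10, thermo).value
    arg = kin.r23_shift + kin.r23_slope * (g2 - g3) / thermo.kt
    rate = 0.5 * kin.r23_max * (1.0 + math.tanh(arg))
    return RateConstant(rate, (2, 3), site.axial, d10)


def detachment_rate_r31(model: CrossBridgeModel, site: TipPosition,
                        d10: float, thermo: ThermoParams,
                        kin: KineticParams = KineticParams()) -> RateConstant:
    """Detachment rate from the post-stroke strain energy at the site.

    ``r31 = r31_rest exp(alpha U3 / kT)``: slowest for an unstrained
    post-stroke head and rising exponentially with the strain needed to
    hold the head at the site.  Position-dependence beyond the energy is
    deliberately absent (the single-spring lineage's explicit axial-offset
    asymmetry does not carry over to multi-spring geometries).
    """
    u3 = geometry.elastic_energy(model, site, 3)
    arg = min(kin.r31_alpha * u3 / thermo.kt, kin.exp_clamp)
    rate = kin.r31_rest * math.exp(arg)
    return RateConstant(rate, (3, 1), site.axial, d10)


def calibrate_detachment(model: CrossBridgeModel, thermo: ThermoParams,
                         rest_d10: float = 34.0, far_d10: float = 38.0,
                         rate_rest: float = 20.0,
                         rate_far: float = 260.0) -> tuple[float, float]:
    """Closed-form calibration of the detachment law ``(r31_rest, alpha)``.

    The detachment floor at rest spacing pins ``r31_rest``; the floor at
    the expanded spacing pins ``alpha`` through the minimal strain energy
    ``U3*`` the head must carry there:

        ``alpha = ln(rate_far / rate_rest) * kT / U3*(far_d10)``.
    """
    corr = lattice.correction_factor(model, rest_d10)
    a3 = energetics.argmin_energy_offset(model, 3, far_d10, corr)
    y = lattice.ssls_from_d10(far_d10, corr)
    u3 = geometry.elastic_energy(model, TipPosition(a3, y), 3)
    alpha = math.log(rate_far / rate_rest) * thermo.kt / u3
    return rate_rest, alpha


# ---------------------------------------------------------------------------
# Reverse rates (detailed balance)

def reverse_rate(forward: RateConstant | float, dg: float,
                 kt: float = 4.11, clamp: float = 50.0) -> RateConstant:
    """Reverse rate from detailed balance.

    ``dg`` is the free-energy change of the *forward* transition in pN nm
    (target minus source state); the reverse rate is
    ``r_rev = r_fwd exp(dg / kT)``, so a strongly downhill forward
    transition has a vanishing reverse.  The exponent is clamped at
    ``+-clamp`` to guard against overflow.
    """
    fwd = float(forward)
    if fwd < 0:
        raise ValueError("forward rate must be non-negative")
    arg = max(-clamp, min(clamp, dg / kt))
    value = fwd * math.exp(arg)
    if isinstance(forward, RateConstant):
        i, j = forward.transition
        return RateConstant(value, (j, i), forward.axial, forward.d10)
    return RateConstant(value, (2, 1))


def rate_table(model: CrossBridgeModel, site: TipPosition, d10: float,
               thermo: ThermoParams, binding: BindingParams,
               kin: KineticParams = KineticParams(),
               rng: np.random.Generator | None = None) -> dict[str, float]:
    """All six rate constants for one binding-site context.

    The 2 -> 1 reverse applies detailed balance to the ensemble attachment
    rate; the 1 -> 3 reverse balances detachment against the full remaining
    ATP budget (a fresh ATP is hydrolysed after detachment), which renders
    it negligible everywhere in the studied window.
    """
    g2 = energetics.free_energy(model, 2, site, d10, thermo).value
    g3 = energetics.free_energy(model, 3, site, d10, thermo).value
    r12 = attachment_rate_r12(model, site, d10, binding, thermo, rng)
    r23 = powerstroke_rate_r23(model, site, d10, thermo, kin)
    r31 = detachment_rate_r31(model, site, d10, thermo, kin)
    r21 = reverse_rate(r12, g2 - 0.0, thermo.kt, kin.exp_clamp)
    r32 = reverse_rate(r23, g3 - g2, thermo.kt, kin.exp_clamp)
    # detachment resets the cycle: the forward drop includes the unspent
    # ATP budget, G1(next cycle) - G3 = -dG_total - G3
    dg31 = -thermo.dg_atp_total * thermo.kt - g3
    r13 = reverse_rate(r31, dg31, thermo.kt, kin.exp_clamp)
    return {"r12": r12.value, "r21": r21.value, "r23": r23.value,
            "r32": r32.value, "r31": r31.value, "r13": r13.value,
            "r12_se": r12.se}


__all__ = [
    "RateConstant", "diffuse", "binding_probability", "attachment_rate_r12",
    "powerstroke_rate_r23", "detachment_rate_r31", "reverse_rate",
    "calibrate_detachment", "rate_table", "rate_from_probability",
    "probability_from_rate",
]
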