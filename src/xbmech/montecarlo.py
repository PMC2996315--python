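"""Time-stepped stochastic simulation of a single cross-bridge.

Each 1 ms step, an unbound head diffuses and tests binding against its
site; a bound head tests its forward transition and then its reverse
(at most one event per step - per-step probabilities are small at 1 ms, so
the resolution order is a second-order detail).  Bound-state rates depend
only on the fixed site context and are precomputed once per simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import energetics, kinetics, lattice
from .params import (BindingParams, CrossBridgeModel, KineticParams,
                     ThermoParams, get_model)

_EVENTS = {(1, 2): "bind", (2, 1): "unbind", (2, 3): "stroke",
           (3, 2): "reverse_stroke", (3, 1): "detach"}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a single-cross-bridge simulation."""

    model: str = "4sXB"
    d10: float = 34.0
    site_axial: float | None = None  # default: pre-stroke energy minimum
    duration: float = 1.0
    seed: int = 0
    thermo: ThermoParams = field(default_factory=ThermoParams)
    kin: KineticParams = field(default_factory=KineticParams)
    ensemble_n: int = 10_000
    tau: float | None = None  # default: the model's standard scale factor

    def __post_init__(self) -> None:
        if self.duration < self.thermo.timestep:
            raise ValueError("duration must cover at least one timestep")


@dataclass(frozen=True)
class Trajectory:
    """Per-step states plus event and occupancy summaries."""

    steps: pd.DataFrame  # time_s, state, axial_nm, radial_nm, event
    summary: dict

    def occupancy(self) -> dict[int, float]:
        frac = self.steps["state"].value_counts(normalize=True)
        return {s: float(frac.get(s, 0.0)) for s in (1, 2, 3)}


def simulate(config: SimConfig) -> Trajectory:
    """Run the three-state cycle for one cross-bridge.

    Identical seed and configuration give byte-identical trajectories.
    """
    model = get_model(config.model)
    thermo, kin = config.thermo, config.kin
    dt = thermo.timestep
    corr = (lattice.correction_factor(model) if model.name != "1sXB"
            else 0.0)
    if config.site_axial is None:
        site_axial = (model.springs[0].rest_pre if model.name == "1sXB" else
                      energetics.argmin_energy_offset(model, 2, config.d10,
                                                      corr))
    else:
        site_axial = config.site_axial
    if model.name == "1sXB":
        site = np.array([site_axial, 0.0])
        site_tip = None
    else:
        site_tip = energetics.site_tip(model, site_axial, config.d10, corr)
        site = site_tip.as_array()
    tau = config.tau if config.tau is not None else (
        BindingParams.for_model(model).tau)

    rng = np.random.default_rng(config.seed)
    binding = BindingParams(tau=tau, ensemble_n=config.ensemble_n,
                            seed=config.seed)
    if model.name == "1sXB":
        rates = _rate_table_1sxb(model, site_axial, config, binding, rng)
    else:
        rates = kinetics.rate_table(model, site_tip, config.d10, thermo,
                                    binding, kin, rng)
    p = {k: kinetics.probability_from_rate(rates[k], dt)
         for k in ("r21", "r23", "r32", "r31", "r13")}

    n = int(round(config.duration / dt))
    times = np.arange(n) * dt
    states = np.empty(n, dtype=np.int8)
    ax = np.empty(n)
    rad = np.empty(n)
    events: list[str] = []

    # pre-draw randomness in bulk for speed and reproducibility
    u_fwd = rng.random(n)
    u_rev = rng.random(n)
    spring_draws = rng.standard_normal((n, len(model.springs)))
    rests2 = np.array([s.rest(2) for s in model.springs])
    sds = np.array([np.sqrt(thermo.kt / s.stiffness)
                    for s in model.springs])

    state = 1
    for i in range(n):
        states[i] = state
        event = "none"
        if state == 1:
            vals = rests2 + sds * spring_draws[i]
            tip = _forward(model, vals)
            ax[i], rad[i] = tip
            pb = float(kinetics.binding_probability(
                tip[None, :], site, tau,
                axial_only=model.name == "1sXB")[0])
            if u_fwd[i] < pb:
                state, event = 2, "bind"
        elif state == 2:
            ax[i], rad[i] = site
            if u_fwd[i] < p["r23"]:
                state, event = 3, "stroke"
            elif u_rev[i] < p["r21"]:
                state, event = 1, "unbind"
        else:
            ax[i], rad[i] = site
            if u_fwd[i] < p["r31"]:
                state, event = 1, "detach"
            elif u_rev[i] < p["r32"]:
                state, event = 2, "reverse_stroke"
        events.append(event)

    steps = pd.DataFrame({"time_s": times, "state": states,
                          "axial_nm": ax, "radial_nm": rad,
                          "event": events})
    occ = steps["state"].value_counts(normalize=True)
    bound = steps["state"] != 1
    counts = steps["event"].value_counts().to_dict()
    counts.pop("none", None)
    summary = {
        "model": model.name, "d10_nm": config.d10,
        "site_axial_nm": float(site_axial), "seed": config.seed,
        "n_steps": n, "duration_s": config.duration,
        "occupancy": {int(s): float(occ.get(s, 0.0)) for s in (1, 2, 3)},
        "fraction_bound": float(bound.mean()),
        "mean_bound_time_s": _mean_bound_time(states, dt),
        "event_counts": counts,
        "rates_per_s": {k: float(v) for k, v in rates.items()
                        if not k.endswith("_se")},
    }
    return Trajectory(steps, summary)


def _forward(model: CrossBridgeModel, vals: np.ndarray) -> np.ndarray:
    if model.name == "1sXB":
        return np.array([vals[0], 0.0])
    if model.name == "2sXB":
        th, arm = vals
        return np.array([arm * np.cos(th), arm * np.sin(th)])
    th1, l2, th3, l4 = vals
    cx, cy = l2 * np.cos(th1), l2 * np.sin(th1)
    return np.array([cx + l4 * np.cos(np.pi - th3),
                     cy + l4 * np.sin(np.pi - th3)])


def _mean_bound_time(states: np.ndarray, dt: float) -> float:
    """Mean duration of contiguous bound (state != 1) stretches, s."""
    bound = states != 1
    if not bound.any():
        return 0.0
    runs = []
    run = 0
    for b in bound:
        if b:
            run += 1
        elif run:
            runs.append(run)
            run = 0
    if run:
        runs.append(run)
    return float(np.mean(runs) * dt)


def _rate_table_1sxb(model: CrossBridgeModel, site_axial: float,
                     config: SimConfig, binding: BindingParams,
                     rng: np.random.Generator) -> dict[str, float]:
    """Bound-state rates for the single-spring reference at a site.

    Uses the same energy-difference laws with the one-dimensional strain
    energies, so the reference model runs through the identical cycle.
    """
    thermo, kin = config.thermo, config.kin
    s = model.springs[0]
    u2 = 0.5 * s.stiffness * (site_axial - s.rest_pre) ** 2
    u3 = 0.5 * s.stiffness * (site_axial - s.rest_post) ** 2
    g2 = thermo.baseline(2) + u2
    g3 = thermo.baseline(3) + u3
    tips = kinetics.diffuse(model, rng, binding.ensemble_n, kt=thermo.kt)
    pbar = float(kinetics.binding_probability(
        tips, np.array([site_axial, 0.0]), binding.tau,
        axial_only=True).mean())
    r12 = kinetics.rate_from_probability(pbar, thermo.timestep)
    arg = kin.r23_shift + kin.r23_slope * (g2 - g3) / thermo.kt
    r23 = 0.5 * kin.r23_max * (1.0 + np.tanh(arg))
    r31 = kin.r31_rest * np.exp(
        min(kin.r31_alpha * u3 / thermo.kt, kin.exp_clamp))
    r21 = float(kinetics.reverse_rate(r12, g2, thermo.kt, kin.exp_clamp))
    r32 = float(kinetics.reverse_rate(r23, g3 - g2, thermo.kt,
                                      kin.exp_clamp))
    r13 = float(kinetics.reverse_rate(
        r31, -thermo.dg_atp_total * thermo.kt - g3, thermo.kt,
        kin.exp_clamp))
    return {"r12": r12, "r21": r21, "r23": float(r23), "r32": r32,
            "r31": float(r31), "r13": r13, "r12_se": 0.0}


__all__ = ["SimConfig", "Trajectory", "simulate"]
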