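"""Landscape scans over axial offset x lattice spacing grids.

Regenerates the energy, rate and force landscapes as rectangular grids and
locates the characteristic axial offsets (energy minima, attachment peak,
power-stroke inflection, detachment floor) per lattice spacing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import energetics, kinetics, lattice
from .geometry import TipPosition
from .params import (BindingParams, CrossBridgeModel, KineticParams,
                     ThermoParams)

_LOG = logging.getLogger(__name__)

#: Layers that need no random numbers and are bit-identical across runs.
DETERMINISTIC_LAYERS = ("energy2", "energy3", "r23", "r31", "r32", "r13",
                        "f_axial", "f_radial")
STOCHASTIC_LAYERS = ("r12", "r21")
ALL_LAYERS = DETERMINISTIC_LAYERS + STOCHASTIC_LAYERS

#: Default grids: the axial window and d10 range of the landscape figures.
DEFAULT_AXIAL = (-5.0, 25.0, 0.25)
DEFAULT_D10 = (30.0, 38.0, 0.5)


@dataclass
class LandscapeGrid:
    """Named layers sampled over an axial-offset x d10 grid.

    ``values[layer]`` has shape ``(len(d10), len(axial))``.  ``mask`` is
    True where the cross-bridge is likely enough to generate force to be of
    interest (all True until :func:`mask_unlikely` is applied).
    """

    axial: np.ndarray
    d10: np.ndarray
    values: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)
    mask: np.ndarray | None = None
    se: dict[str, np.ndarray] = field(default_factory=dict)

    def layer(self, name: str) -> np.ndarray:
        return self.values[name]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per (d10, axial) cell."""
        dd, aa = np.meshgrid(self.d10, self.axial, indexing="ij")
        data = {"model": self.provenance.get("model", ""),
                "d10_nm": dd.ravel(), "axial_nm": aa.ravel()}
        for name, arr in self.values.items():
            data[name] = arr.ravel()
        for name, arr in self.se.items():
            data[name + "_se"] = arr.ravel()
        if self.mask is not None:
            data["likely"] = self.mask.ravel()
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _grid(spec: tuple[float, float, float]) -> np.ndarray:
    lo, hi, step = spec
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def scan_landscape(model: CrossBridgeModel,
                   layers=ALL_LAYERS,
                   axial: tuple[float, float, float] = DEFAULT_AXIAL,
                   d10: tuple[float, float, float] = DEFAULT_D10,
                   thermo: ThermoParams | None = None,
                   binding: BindingParams | None = None,
                   kin: KineticParams | None = None,
                   seed: int = 0) -> LandscapeGrid:
    """Evaluate the requested layers at every grid cell.

    Deterministic layers (energies, energy-driven rates, forces) are exact;
    the attachment rate and its detailed-balance reverse are Monte-Carlo
    estimates with a per-(cell) seeded stream and a standard-error layer.
    Solver failures are recorded as NaN, not raised.
    """
    thermo = thermo or ThermoParams()
    kin = kin or KineticParams()
    binding = binding or BindingParams.for_model(model, seed=seed)
    ax = _grid(axial)
    dd = _grid(d10)
    corr = (lattice.correction_factor(model)
            if model.name != "1sXB" else 0.0)
    out = {name: np.full((dd.size, ax.size), np.nan) for name in layers}
    se = {name: np.full((dd.size, ax.size), np.nan)
          for name in layers if name in STOCHASTIC_LAYERS}
    want_mc = any(name in STOCHASTIC_LAYERS for name in layers)
    n_failed = 0

    for i, d in enumerate(dd):
        if model.name == "1sXB":
            y = None
        else:
            y = lattice.ssls_from_d10(d, corr)
        # one diffusion ensemble per d10 row: the cloud is site-independent
        if want_mc:
            rng = np.random.default_rng((seed, i))
            tips = kinetics.diffuse(model, rng, binding.ensemble_n,
                                    kt=thermo.kt)
        for j, a in enumerate(ax):
            try:
                row = _cell(model, a, y, d, layers, thermo, binding, kin,
                            tips if want_mc else None)
            except Exception as exc:
                n_failed += 1
                _LOG.warning("cell (d10=%.2f, axial=%.2f) failed: %s",
                             d, a, exc)
                continue
            for name, v in row.items():
                if name.endswith("_se"):
                    se[name[:-3]][i, j] = v
                else:
                    out[name][i, j] = v
    prov = {"model": model.name, "seed": seed, "failed_cells": n_failed,
            "axial": list(axial), "d10": list(d10),
            "ensemble_n": binding.ensemble_n, "tau": binding.tau,
            "params_hash": _params_hash(model, thermo, kin)}
    return LandscapeGrid(ax, dd, out, provenance=prov, se=se)


def _cell(model, a, y, d, layers, thermo, binding, kin, tips):
    from . import geometry

    if model.name == "1sXB":
        s = model.springs[0]
        u2 = 0.5 * s.stiffness * (a - s.rest_pre) ** 2
        u3 = 0.5 * s.stiffness * (a - s.rest_post) ** 2
        f = (-s.stiffness * (a - s.rest_post), 0.0)
        site = np.array([a, 0.0])
    else:
        tip = TipPosition(a, y)
        u2 = geometry.elastic_energy(model, tip, 2)
        u3 = geometry.elastic_energy(model, tip, 3)
        f = tuple(energetics.reaction_force(model, 3, tip, d))
        site = np.array([a, y])
    g2 = thermo.baseline(2) + u2
    g3 = thermo.baseline(3) + u3
    row: dict[str, float] = {}
    if "energy2" in layers:
        row["energy2"] = g2
    if "energy3" in layers:
        row["energy3"] = g3
    if "f_axial" in layers:
        row["f_axial"] = f[0]
    if "f_radial" in layers:
        row["f_radial"] = f[1]
    if "r23" in layers or "r32" in layers:
        arg = kin.r23_shift + kin.r23_slope * (g2 - g3) / thermo.kt
        r23 = 0.5 * kin.r23_max * (1.0 + np.tanh(arg))
        if "r23" in layers:
            row["r23"] = r23
        if "r32" in layers:
            row["r32"] = float(kinetics.reverse_rate(
                r23, g3 - g2, thermo.kt, kin.exp_clamp))
    if "r31" in layers or "r13" in layers:
        r31 = kin.r31_rest * np.exp(
            min(kin.r31_alpha * u3 / thermo.kt, kin.exp_clamp))
        if "r31" in layers:
            row["r31"] = r31
        if "r13" in layers:
            row["r13"] = float(kinetics.reverse_rate(
                r31, -thermo.dg_atp_total * thermo.kt - g3, thermo.kt,
                kin.exp_clamp))
    if tips is not None and ("r12" in layers or "r21" in layers):
        p = kinetics.binding_probability(tips, site, binding.tau,
                                         axial_only=model.name == "1sXB")
        pbar = float(p.mean())
        r12 = kinetics.rate_from_probability(pbar, thermo.timestep)
        se_p = float(p.std(ddof=1) / np.sqrt(p.size))
        se_r = se_p / ((1.0 - pbar) * thermo.timestep) if pbar < 1 else np.inf
        if "r12" in layers:
            row["r12"] = r12
            row["r12_se"] = se_r
        if "r21" in layers:
            row["r21"] = float(kinetics.reverse_rate(
                r12, g2, thermo.kt, kin.exp_clamp))
            row["r21_se"] = se_r
    return row


def _params_hash(model, thermo, kin) -> str:
    blob = json.dumps([repr(model), repr(thermo), repr(kin)]).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Summaries

@dataclass(frozen=True)
class AxialOffsetSummary:
    """Characteristic axial offsets per lattice spacing."""

    table: pd.DataFrame  # d10_nm, argmin_energy2, argmin_energy3,
    #                      argmax_r12, inflection_r23, argmin_r31, step_nm

    def step_curve(self) -> pd.Series:
        return self.table.set_index("d10_nm")["step_nm"]


def _refine_extremum(x: np.ndarray, yv: np.ndarray, idx: int) -> float:
    """Parabolic refinement of a grid extremum location."""
    if idx == 0 or idx == len(x) - 1:
        return float(x[idx])
    y0, y1, y2 = yv[idx - 1], yv[idx], yv[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0 or not np.isfinite(denom):
        return float(x[idx])
    return float(x[idx] + 0.5 * (y0 - y2) / denom * (x[1] - x[0]))


def summarize_offsets(grid: LandscapeGrid) -> AxialOffsetSummary:
    """Locate per-d10 extrema (refined around the best grid cell)."""
    rows = []
    ax = grid.axial
    for i, d in enumerate(grid.d10):
        rec: dict[str, float] = {"d10_nm": float(d)}
        for name, col in (("energy2", "argmin_energy2"),
                          ("energy3", "argmin_energy3"),
                          ("r31", "argmin_r31")):
            if name in grid.values:
                v = grid.values[name][i]
                k = int(np.nanargmin(v))
                rec[col] = _refine_extremum(ax, v, k)
        if "r12" in grid.values:
            v = grid.values["r12"][i]
            k = int(np.nanargmax(v))
            rec["argmax_r12"] = _refine_extremum(ax, -v, k)
        if "r23" in grid.values:
            v = grid.values["r23"][i]
            dv = np.gradient(v, ax)
            k = int(np.nanargmax(np.abs(dv)))
            rec["inflection_r23"] = float(ax[k])
        if "argmin_energy2" in rec and "argmin_energy3" in rec:
            rec["step_nm"] = rec["argmin_energy2"] - rec["argmin_energy3"]
        rows.append(rec)
    return AxialOffsetSummary(pd.DataFrame(rows))


def mask_unlikely(grid: LandscapeGrid, threshold: float | None = None,
                  flux_retained: float = 0.95) -> LandscapeGrid:
    """Mask cells where the cross-bridge is unlikely to generate force.

    The likelihood score combines how readily a cross-bridge arrives (the
    attachment rate) with how long it stays (the inverse detachment rate);
    both are normalised to their grid maxima before summing so the score is
    dimensionless.  With ``threshold=None`` the threshold is set to the
    largest value that keeps at least ``flux_retained`` of the total
    attachment flux; ``threshold=0`` keeps every cell.  The rule and
    threshold are recorded in the grid provenance.
    """
    r12, r31 = grid.values["r12"], grid.values["r31"]
    with np.errstate(divide="ignore"):
        stay = 1.0 / r31
    score = (np.nan_to_num(r12 / np.nanmax(r12))
             + np.nan_to_num(stay / np.nanmax(stay)))
    if threshold is None:
        flux = np.nan_to_num(r12)
        order = np.argsort(score.ravel())[::-1]
        csum = np.cumsum(flux.ravel()[order])
        k = int(np.searchsorted(csum, flux_retained * flux.sum()))
        k = min(k, order.size - 1)
        threshold = float(score.ravel()[order[k]])
    mask = score >= threshold
    prov = dict(grid.provenance)
    prov["mask_rule"] = ("normalized r12 + 1/r31 >= threshold")
    prov["mask_threshold"] = float(threshold)
    return LandscapeGrid(grid.axial, grid.d10, grid.values, prov, mask,
                         grid.se)


# ---------------------------------------------------------------------------
# CSV output schemas

def write_energy_csv(grid: LandscapeGrid, path) -> None:
    """Energy/force landscape CSV: one row per (state, d10, axial)."""
    rows = []
    dd, aa = np.meshgrid(grid.d10, grid.axial, indexing="ij")
    for state, lname in ((2, "energy2"), (3, "energy3")):
        if lname not in grid.values:
            continue
        fax = grid.values.get("f_axial")
        frad = grid.values.get("f_radial")
        rows.append(pd.DataFrame({
            "model": grid.provenance.get("model", ""), "state": state,
            "d10_nm": dd.ravel(), "axial_nm": aa.ravel(),
            "energy_pNnm": grid.values[lname].ravel(),
            "f_axial_pN": (fax.ravel() if state == 3 and fax is not None
                           else np.nan),
            "f_radial_pN": (frad.ravel() if state == 3 and frad is not None
                            else np.nan)}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def write_rate_csv(grid: LandscapeGrid, path) -> None:
    """Rate-map CSV: model, transition, d10_nm, axial_nm, rate, SE, n, seed."""
    dd, aa = np.meshgrid(grid.d10, grid.axial, indexing="ij")
    n = grid.provenance.get("ensemble_n", 0)
    seed = grid.provenance.get("seed", 0)
    rows = []
    for name in ("r12", "r21", "r23", "r32", "r31", "r13"):
        if name not in grid.values:
            continue
        se = grid.se.get(name)
        rows.append(pd.DataFrame({
            "model": grid.provenance.get("model", ""), "transition": name,
            "d10_nm": dd.ravel(), "axial_nm": aa.ravel(),
            "rate_per_s": grid.values[name].ravel(),
            "se_per_s": se.ravel() if se is not None else 0.0,
            "n": n if name in STOCHASTIC_LAYERS else 0,
            "seed": seed if name in STOCHASTIC_LAYERS else ""}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


__all__ = ["LandscapeGrid", "AxialOffsetSummary", "scan_landscape",
           "summarize_offsets", "mask_unlikely", "write_energy_csv",
           "write_rate_csv", "ALL_LAYERS", "DETERMINISTIC_LAYERS",
           "STOCHASTIC_LAYERS", "DEFAULT_AXIAL", "DEFAULT_D10"]
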