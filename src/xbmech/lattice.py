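"""Lattice-spacing conversion between the model-internal surface-to-surface
spacing (ssLS) and the x-ray diffraction d10 measurement.

In the hexagonal myofilament lattice the nearest thick-to-thin
center-to-center distance is ``2 d10 / 3``.  The model works with the
surface-to-surface gap the cross-bridge actually spans, so

    ``d10 = (3/2) (ssLS + c)``

where the correction factor ``c`` absorbs the filament radii.  ``c`` is not
taken from electron micrographs; it is calibrated mechanically, so that at
rest lattice spacing the post-power-stroke cross-bridge sitting at its
unstrained axial offset generates neither compressive nor expansive radial
force.  With the standard 4sXB geometry and a 34 nm rest d10 this yields
c = 6.90 nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

from scipy.optimize import brentq

from . import geometry
from .params import CrossBridgeModel

#: d10 window studied, nm; values outside warn but compute.
D10_WINDOW = (30.0, 38.0)

#: Hexagonal-lattice ratio between d10 and the thick-thin center distance.
_LATTICE_FACTOR = 1.5


def d10_from_ssls(ssls: float, correction: float) -> float:
    """d10 (nm) from a surface-to-surface spacing and correction factor."""
    if ssls <= 0:
        raise ValueError("surface-to-surface spacing must be positive")
    return _LATTICE_FACTOR * (ssls + correction)


def ssls_from_d10(d10: float, correction: float) -> float:
    """Surface-to-surface spacing (nm) from a d10 value."""
    ssls = d10 / _LATTICE_FACTOR - correction
    if ssls <= 0:
        raise ValueError(
            f"d10 = {d10} nm maps to non-physical ssLS {ssls:.3f} nm")
    return ssls


@lru_cache(maxsize=16)
def correction_factor(model: CrossBridgeModel, rest_d10: float = 34.0) -> float:
    """Calibrate the filament-radius correction factor, nm.

    Finds the surface-to-surface spacing at which the post-power-stroke
    cross-bridge, held at its unstrained axial offset, exerts zero radial
    force, and returns the offset mapping that spacing to ``rest_d10``.
    """
    if model.name == "1sXB":
        raise ValueError("the 1sXB generates no radial force to calibrate on")
    rest = geometry.rest_tip(model, 3)

    def radial_force(y: float) -> float:
        tip = geometry.TipPosition(rest.axial, y)
        return -geometry.elastic_gradient(model, tip, 3)[1]

    lo, hi = geometry.MIN_RADIAL + 0.6, 60.0
    try:
        y0 = brentq(radial_force, lo, hi, xtol=1e-10)
    except ValueError as exc:
        raise RuntimeError(
            "no zero-radial-force spacing in the physical window") from exc
    return rest_d10 / _LATTICE_FACTOR - y0


@dataclass(frozen=True)
class LatticeSpacing:
    """A lattice spacing under a fixed calibration.

    Stores the d10 value, its surface-to-surface equivalent, and the
    correction factor tying them together.
    """

    d10: float
    ssls: float
    correction: float

    def __post_init__(self) -> None:
        expected = d10_from_ssls(self.ssls, self.correction)
        if abs(expected - self.d10) > 1e-9:
            raise ValueError("inconsistent d10 / ssLS / correction triple")
        if not (D10_WINDOW[0] <= self.d10 <= D10_WINDOW[1]):
            warnings.warn(
                f"d10 = {self.d10} nm is outside the studied window "
                f"{D10_WINDOW}", stacklevel=2)

    @classmethod
    def from_d10(cls, d10: float, correction: float) -> "LatticeSpacing":
        return cls(d10, ssls_from_d10(d10, correction), correction)

    @classmethod
    def calibrated(cls, model: CrossBridgeModel, d10: float,
                   rest_d10: float = 34.0) -> "LatticeSpacing":
        """Spacing under the model's own zero-radial-force calibration."""
        return cls.from_d10(d10, correction_factor(model, rest_d10))


__all__ = ["LatticeSpacing", "correction_factor", "d10_from_ssls",
           "ssls_from_d10", "D10_WINDOW"]
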