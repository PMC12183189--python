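"""Water relations: turgor, osmotic adjustment and solute deposition.

Turgor pressure is the difference between tissue water potential and
osmotic potential, ``psi_p = psi_w - psi_s`` (MPa).  Osmotic adjustment
is complete when the drop in water potential under stress is matched by
an equal drop in osmotic potential so that turgor is maintained.

The solute-deposition computation is a steady-state continuity
framework: with concentration ``c``, cross-sectional area ``A`` and
displacement velocity ``v`` on a shared position grid, the net local
deposition rate is the spatial derivative of the solute flux,
``D(x) = d(c A v)/dx``.  It lets the two routes to increased solute
concentration -- more deposition versus less water (dilution) -- be
separated on synthetic fields; it is a framework, not a reproduced
measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import REGION_BOUNDS
from .kinematics import region_summaries

__all__ = [
    "TissueWaterStatus",
    "SoluteField",
    "WaterError",
    "turgor",
    "osmotic_adjustment",
    "deposition_rate",
]


class WaterError(ValueError):
    pass


@dataclass
class TissueWaterStatus:
    """Water, osmotic and (derived) turgor potential of one tissue, MPa."""

    tissue: str
    treatment: str
    psi_w: float
    psi_s: float | None = None

    def __post_init__(self) -> None:
        if self.psi_w > 0:
            warnings.warn(f"psi_w = {self.psi_w} MPa > 0 for {self.tissue}", stacklevel=2)

    @property
    def psi_p(self) -> float:
        if self.psi_s is None:
            raise WaterError(f"no osmotic potential recorded for {self.tissue}")
        return turgor(self.psi_w, self.psi_s)


@dataclass
class SoluteField:
    """Solute concentration, area and velocity profiles on one grid.

    Concentration units are opaque but must be consistent; areas in mm^2,
    velocity in mm/h, positions in mm.
    """

    position_mm: np.ndarray
    concentration: np.ndarray
    area_mm2: np.ndarray
    velocity_mm_h: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in
                  (self.position_mm, self.concentration, self.area_mm2, self.velocity_mm_h)]
        self.position_mm, self.concentration, self.area_mm2, self.velocity_mm_h = arrays
        n = self.position_mm.size
        if any(a.size != n for a in arrays):
            raise WaterError("field profiles must share one grid")
        if np.any(self.concentration < 0) or np.any(self.area_mm2 < 0):
            raise WaterError("concentration and area must be non-negative")

    @property
    def flux(self) -> np.ndarray:
        """Solute flux c * A * v along the axis."""
        return self.concentration * self.area_mm2 * self.velocity_mm_h


def turgor(psi_w: float, psi_s: float) -> float:
    """Turgor pressure psi_p = psi_w - psi_s (MPa)."""
    return psi_w - psi_s


def osmotic_adjustment(ww: TissueWaterStatus, wd: TissueWaterStatus,
                       tolerance_mpa: float = 0.05) -> tuple[float, bool]:
    """Osmotic adjustment between control and stressed tissue.

    Returns ``(delta_psi_s, complete)``: the decrease in osmotic potential
    under stress (positive when psi_s fell) and whether turgor was
    maintained within ``tolerance_mpa`` (complete adjustment).
    """
    if ww.psi_s is None or wd.psi_s is None:
        raise WaterError("both statuses need an osmotic potential")
    delta = ww.psi_s - wd.psi_s
    complete = abs(wd.psi_p - ww.psi_p) <= tolerance_mpa
    return delta, complete


def deposition_rate(field: SoluteField, smooth: int = 1,
                    scheme: dict[str, tuple[float, float]] | None = None):
    """Net solute deposition D(x) = d(c A v)/dx with per-region integrals.

    Returns ``(D, per_region)`` where ``per_region`` maps region name to
    the integral of D over that region (equal, by the fundamental theorem
    of calculus, to the flux difference across it).  A short boxcar smooth
    (odd width ``smooth``; 1 disables) can be applied to the flux before
    differencing when the inputs are noisy.
    """
    x = field.position_mm
    flux = field.flux
    if smooth > 1:
        if smooth % 2 == 0:
            smooth += 1
        pad = smooth // 2
        flux = np.convolve(np.pad(flux, pad, mode="edge"),
                           np.ones(smooth) / smooth, mode="valid")
    D = np.gradient(flux, x)
    scheme = scheme or REGION_BOUNDS
    summaries = region_summaries(x, {"deposition": D}, scheme=scheme)
    per_region = {r: s["deposition"]["integral"] for r, s in summaries.items()}
    return D, per_region
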