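"""Kinematic analysis of the root growth zone.

The growing root is treated as a material continuum: a tissue element at
position ``x`` (mm from the root-cap junction) is displaced away from the
tip with velocity ``v(x)``, and spatial derivatives of ``v`` give local
expansion rates.  Under steady-state growth the cell flux (cells per file
per hour leaving the growth zone) is constant along a cell file, which
allows the displacement-velocity profile to be reconstructed from a
cortical cell-length profile and the overall elongation rate:

    flux = E / l_final         (cells/h; E in mm/h, l_final in mm)
    v(x) = flux * l(x)

A four-parameter logistic ``v(x) = a2 + (a1 - a2)/(1 + (x/x0)**p)`` is
fitted to the velocity points; its analytic derivative is the relative
elongation rate (REL, 1/h).  Radial plus tangential expansion is
``v * d ln A/dx`` with ``A`` the cross-sectional area, and the volumetric
expansion rate is ``(REL + radtan) * A`` (mm^3 per mm root length per h).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .config import REGION_BOUNDS

__all__ = [
    "AxialLengthCohort",
    "CellLengthProfile",
    "DiameterProfile",
    "VelocityProfile",
    "LogisticFit",
    "ExpansionProfileSet",
    "KinematicsError",
    "elongation_rate",
    "mature_cell_length",
    "cell_flux",
    "velocity_profile",
    "logistic_velocity",
    "fit_logistic",
    "rel_profile",
    "growth_zone_extent",
    "area_profile",
    "radtan_rate",
    "volumetric_profiles",
    "region_summaries",
]

GRID_STEP_MM = 0.1  # common resampling step for profile algebra
PROFILE_MAX_MM = 12.0  # cell elongation has ceased by ~10-12 mm
MATURE_WINDOW_MM = (10.0, 12.0)


class KinematicsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# containers


@dataclass
class AxialLengthCohort:
    """Per-plant axial root lengths at the two harvest days (15 and 17)."""

    plant: np.ndarray  # plant ids (str)
    day: np.ndarray  # int, 15 or 17
    treatment: np.ndarray  # str labels
    length_cm: np.ndarray

    def __post_init__(self) -> None:
        self.plant = np.asarray(self.plant)
        self.day = np.asarray(self.day, dtype=int)
        self.treatment = np.asarray(self.treatment)
        self.length_cm = np.asarray(self.length_cm, dtype=float)
        if np.any(self.length_cm <= 0):
            raise KinematicsError("root lengths must be positive")

    def lengths_on(self, day: int) -> np.ndarray:
        return self.length_cm[self.day == day]


@dataclass
class _PositionProfile:
    position_mm: np.ndarray
    value: np.ndarray
    treatment: str = ""
    day: int | None = None

    def __post_init__(self) -> None:
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.position_mm.shape != self.value.shape:
            raise KinematicsError("position and value arrays must match")
        if np.any(np.diff(self.position_mm) <= 0):
            raise KinematicsError("positions must be strictly increasing")


@dataclass
class CellLengthProfile(_PositionProfile):
    """Cortical cell length (um) vs position (mm from the root-cap junction)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.position_mm.size and (
            self.position_mm[0] < 0 or self.position_mm[-1] > PROFILE_MAX_MM
        ):
            raise KinematicsError(f"cell-length positions must lie in [0, {PROFILE_MAX_MM}] mm")

    @property
    def cell_length_um(self) -> np.ndarray:
        return self.value


@dataclass
class DiameterProfile(_PositionProfile):
    """Root diameter (mm) vs position (mm)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.value <= 0):
            raise KinematicsError("diameters must be positive")

    @property
    def diameter_mm(self) -> np.ndarray:
        return self.value


@dataclass
class VelocityProfile(_PositionProfile):
    """Displacement velocity (mm/h) vs position (mm)."""

    @property
    def velocity_mm_h(self) -> np.ndarray:
        return self.value


@dataclass
class LogisticFit:
    """Fitted logistic displacement-velocity curve.

    ``a1`` is the tip asymptote and ``a2`` the mature plateau (mm/h),
    ``x0`` the midpoint (mm), ``p`` the steepness, ``r`` the Pearson
    correlation between observed and fitted velocities.
    """

    a1: float
    a2: float
    x0: float
    p: float
    r: float
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.a2 > self.a1 >= 0):
            raise KinematicsError("logistic fit requires a2 > a1 >= 0")
        if self.x0 <= 0 or self.p <= 0:
            raise KinematicsError("logistic fit requires x0 > 0 and p > 0")
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise KinematicsError("R must lie in [-1, 1]")

    def velocity(self, x) -> np.ndarray:
        return logistic_velocity(np.asarray(x, dtype=float), self.a1, self.a2, self.x0, self.p)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"a1": self.a1, "a2": self.a2, "x0": self.x0, "p": self.p,
                 "r": self.r, "converged": self.converged},
                fh, indent=2,
            )


@dataclass
class ExpansionProfileSet:
    """Bundle of expansion-rate profiles on a shared position grid.

    Invariants ``relvol == rel + radtan`` and ``volrate == relvol * area``
    are enforced at construction.
    """

    position_mm: np.ndarray
    rel: np.ndarray  # 1/h
    radtan: np.ndarray  # 1/h
    relvol: np.ndarray  # 1/h
    area_mm2: np.ndarray
    volrate: np.ndarray  # mm^3 mm^-1 h^-1
    peak_position_mm: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        arrays = [self.position_mm, self.rel, self.radtan, self.relvol, self.area_mm2, self.volrate]
        for i, a in enumerate(arrays):
            arrays[i] = np.asarray(a, dtype=float)
        (self.position_mm, self.rel, self.radtan, self.relvol,
         self.area_mm2, self.volrate) = arrays
        n = self.position_mm.size
        if any(a.size != n for a in arrays):
            raise KinematicsError("profiles must share one grid")
        if not np.allclose(self.relvol, self.rel + self.radtan, atol=1e-9):
            raise KinematicsError("identity violated: relvol must equal rel + radtan")
        if not np.allclose(self.volrate, self.relvol * self.area_mm2, atol=1e-9):
            raise KinematicsError("identity violated: volrate must equal relvol * area")


# ---------------------------------------------------------------------------
# elongation rate, mature cell length, flux


def elongation_rate(cohort: AxialLengthCohort) -> tuple[float, float]:
    """Overall elongation rate from the day-15 / day-17 mean lengths.

    Returns ``(cm/day, mm/h)``: the mean length difference divided by the
    two-day interval.
    """
    l15 = cohort.lengths_on(15)
    l17 = cohort.lengths_on(17)
    if l15.size == 0 or l17.size == 0:
        raise KinematicsError("cohort must contain plants harvested on both day 15 and day 17")
    rate_cm_day = (l17.mean() - l15.mean()) / 2.0
    if rate_cm_day < 0:
        warnings.warn("computed elongation rate is negative", stacklevel=2)
    return rate_cm_day, rate_cm_day * 10.0 / 24.0


def mature_cell_length(profile: CellLengthProfile,
                       window: tuple[float, float] = MATURE_WINDOW_MM) -> float:
    """Mean cell length (um) over the mature window (default 10-12 mm)."""
    lo, hi = window
    mask = (profile.position_mm >= lo) & (profile.position_mm <= hi)
    if mask.sum() < 2:
        raise KinematicsError(f"need >= 2 profile points in the mature window {window}")
    return float(profile.cell_length_um[mask].mean())


def cell_flux(rate_mm_h: float, final_cell_len_um: float) -> float:
    """Cell flux (cells/h) = elongation rate / final cell length."""
    if final_cell_len_um <= 0:
        raise KinematicsError("final cell length must be positive")
    return rate_mm_h / (final_cell_len_um / 1000.0)


def velocity_profile(profile: CellLengthProfile, rate_mm_h: float,
                     mature_window: tuple[float, float] = MATURE_WINDOW_MM,
                     rel_tol: float = 0.05,
                     l_final_um: float | None = None) -> VelocityProfile:
    """Reconstruct displacement velocity from a cell-length profile.

    Flux constancy along the cell file gives ``v(x) = flux * l(x)`` with
    ``flux = rate / l_final``; at mature positions ``v`` equals the overall
    elongation rate.  ``l_final_um`` overrides the mature-window estimate
    (useful when the profile does not reach the mature zone).
    """
    l_final = l_final_um if l_final_um is not None else mature_cell_length(profile, mature_window)
    if np.any(profile.cell_length_um > l_final * (1.0 + rel_tol)):
        warnings.warn("cell lengths exceed the mature mean by more than the tolerance; "
                      "velocities above the overall rate will result", stacklevel=2)
    flux = cell_flux(rate_mm_h, l_final)
    v = flux * profile.cell_length_um / 1000.0
    return VelocityProfile(profile.position_mm, v, profile.treatment, profile.day)


# ---------------------------------------------------------------------------
# logistic fitting and the REL profile


def logistic_velocity(x, a1: float, a2: float, x0: float, p: float):
    x = np.asarray(x, dtype=float)
    return a2 + (a1 - a2) / (1.0 + (x / x0) ** p)


def fit_logistic(vel: VelocityProfile, init: tuple[float, float, float, float] | None = None,
                 n_restarts: int = 4) -> LogisticFit:
    """Least-squares fit of the logistic curve to a velocity profile.

    Initialisation: ``a1 = min(v)``, ``a2 = max(v)``, ``x0`` at the
    half-range crossing, ``p = 4``; bounded so that a2 > a1 >= 0 and
    x0, p > 0, with a fixed restart schedule (perturbed x0/p) on failure.
    R is the Pearson correlation between observed and fitted velocities.
    """
    x = vel.position_mm
    y = vel.velocity_mm_h
    if x.size < 5:
        raise KinematicsError("need >= 5 velocity points to fit the logistic")
    span = y.max() - y.min()
    if span <= 0 or span < 1e-9 * max(abs(y.max()), 1.0):
        raise KinematicsError("degenerate (flat) velocity data")
    if init is None:
        half = y.min() + span / 2.0
        above = np.nonzero(y >= half)[0]
        x0_init = float(x[above[0]]) if above.size else float(np.median(x))
        init = (float(y.min()), float(y.max()), max(x0_init, 1e-3), 4.0)
    lower = [0.0, 1e-9, 1e-6, 1e-6]
    upper = [np.inf, np.inf, np.inf, 50.0]
    rng = np.random.default_rng(0)  # fixed restart schedule
    last_err: Exception | None = None
    for attempt in range(n_restarts + 1):
        p0 = list(init)
        if attempt > 0:
            p0[2] *= float(rng.uniform(0.5, 2.0))
            p0[3] = float(rng.uniform(1.5, 8.0))
        p0[1] = max(p0[1], p0[0] + 1e-6)
        try:
            popt, _ = optimize.curve_fit(
                logistic_velocity, x, y, p0=p0,
                bounds=(lower, upper), maxfev=20000,
            )
            a1, a2, x0, p = (float(v) for v in popt)
            if a2 <= a1:
                raise RuntimeError("fit collapsed: a2 <= a1")
            fitted = logistic_velocity(x, a1, a2, x0, p)
            if np.std(fitted) == 0:
                r = 0.0
            else:
                r = float(stats.pearsonr(y, fitted)[0])
            return LogisticFit(a1=a1, a2=a2, x0=x0, p=p, r=min(r, 1.0))
        except (RuntimeError, optimize.OptimizeWarning) as err:  # pragma: no cover - rare
            last_err = err
    raise KinematicsError(f"logistic fit did not converge after {n_restarts + 1} attempts: {last_err}")


def rel_profile(fit: LogisticFit, grid_mm) -> np.ndarray:
    """Relative elongation rate (1/h): analytic dv/dx of the fitted logistic.

    dv/dx = (a2 - a1) * p * (x/x0)**(p-1) / (x0 * (1 + (x/x0)**p)**2)
    """
    x = np.asarray(grid_mm, dtype=float)
    if np.any(x < 0):
        raise KinematicsError("positions must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (x / fit.x0) ** fit.p
        rel = (fit.a2 - fit.a1) * fit.p * (x / fit.x0) ** (fit.p - 1) / (fit.x0 * (1.0 + u) ** 2)
    # x = 0 limit: 0 for p > 1, finite for p == 1
    rel = np.where(np.isfinite(rel), rel, 0.0)
    return rel


def growth_zone_extent(grid_mm, rel, frac: float = 0.05) -> tuple[float, float, float]:
    """Extent of the growth zone from the REL profile.

    Returns ``(extent_mm, peak_position_mm, peak_value)`` where the extent
    is the smallest position beyond the REL peak at which the REL falls
    below ``frac`` of its peak value.  Raises if the profile has no
    interior maximum (no deceleration phase).
    """
    x = np.asarray(grid_mm, dtype=float)
    r = np.asarray(rel, dtype=float)
    i_pk = int(np.argmax(r))
    peak = float(r[i_pk])
    if peak <= 0 or np.allclose(r, r[0]):
        raise KinematicsError("no deceleration phase: REL profile has no interior maximum")
    if i_pk == r.size - 1:
        raise KinematicsError("no deceleration phase: REL still rising at the end of the grid")
    below = np.nonzero(r[i_pk:] < frac * peak)[0]
    if below.size == 0:
        raise KinematicsError(
            f"REL does not fall below {frac:.0%} of its peak within the grid; extend the grid")
    j = i_pk + below[0]
    # linear interpolation between the bracketing grid points
    x1, x2 = x[j - 1], x[j]
    r1, r2 = r[j - 1], r[j]
    extent = float(x1 + (frac * peak - r1) * (x2 - x1) / (r2 - r1)) if r2 != r1 else float(x2)
    return extent, float(x[i_pk]), peak


# ---------------------------------------------------------------------------
# radial + tangential and volumetric expansion


def area_profile(diam: DiameterProfile) -> np.ndarray:
    """Cross-sectional area (mm^2) assuming a circular section: pi d^2 / 4."""
    return np.pi * diam.diameter_mm ** 2 / 4.0


def _smoothed_gradient(y: np.ndarray, x: np.ndarray, smooth: int = 5) -> np.ndarray:
    """Central-difference gradient after a light moving-average smooth.

    Diameter data are noisy and d ln A/dx amplifies noise, so the signal is
    smoothed with a short boxcar (odd width ``smooth``; 1 disables) before
    differencing.
    """
    if smooth > 1:
        if smooth % 2 == 0:
            smooth += 1
        pad = smooth // 2
        ypad = np.pad(y, pad, mode="edge")
        kernel = np.ones(smooth) / smooth
        y = np.convolve(ypad, kernel, mode="valid")
    return np.gradient(y, x)


def radtan_rate(vel: VelocityProfile, area_mm2, smooth: int = 5) -> np.ndarray:
    """Radial plus tangential expansion rate (1/h): v * d ln A / dx."""
    area = np.asarray(area_mm2, dtype=float)
    if area.shape != vel.position_mm.shape:
        raise KinematicsError("velocity and area profiles must share one grid")
    if np.any(area <= 0):
        raise KinematicsError("areas must be positive")
    dlnA = _smoothed_gradient(np.log(area), vel.position_mm, smooth=smooth)
    return vel.velocity_mm_h * dlnA


def volumetric_profiles(grid_mm, rel, radtan, area_mm2) -> ExpansionProfileSet:
    """Combine REL and radial+tangential rates into volumetric profiles.

    ``relvol = rel + radtan`` (1/h) and ``volrate = relvol * area``
    (mm^3 per mm root length per h, taking root volume per unit length as
    the cross-sectional area of a cylinder).  The position of the volrate
    peak is recorded.
    """
    x = np.asarray(grid_mm, dtype=float)
    rel = np.asarray(rel, dtype=float)
    radtan = np.asarray(radtan, dtype=float)
    area = np.asarray(area_mm2, dtype=float)
    if not (x.shape == rel.shape == radtan.shape == area.shape):
        raise KinematicsError("profiles must share one grid")
    relvol = rel + radtan
    volrate = relvol * area
    peak = float(x[int(np.argmax(volrate))])
    return ExpansionProfileSet(x, rel, radtan, relvol, area, volrate, peak_position_mm=peak)


def region_summaries(grid_mm, profiles: dict[str, np.ndarray],
                     scheme: dict[str, tuple[float, float]] | None = None) -> dict:
    """Per-region trapezoidal integrals and means of each named profile."""
    scheme = scheme or REGION_BOUNDS
    x = np.asarray(grid_mm, dtype=float)
    out: dict[str, dict[str, dict[str, float]]] = {}
    for region, (lo, hi) in scheme.items():
        if lo < x[0] - 1e-9 or hi > x[-1] + 1e-9:
            raise KinematicsError(f"region {region} [{lo}, {hi}] lies outside the grid")
        mask = (x >= lo - 1e-12) & (x <= hi + 1e-12)
        xr = x[mask]
        out[region] = {}
        for name, prof in profiles.items():
            yr = np.asarray(prof, dtype=float)[mask]
            integral = float(np.trapezoid(yr, xr))
            out[region][name] = {"integral": integral, "mean": float(yr.mean())}
    return out
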