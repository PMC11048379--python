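"""Boltzmann sigmoid fits to educt breakdown courses.

The normalized educt intensity vs ΔCV follows

    y(x) = Final + (Initial - Final) / (1 + exp((x - dcv50) / dx))

with plateaus Initial (low ΔCV) and Final (high ΔCV), midpoint dcv50 and
width dx.  The analytic tangent at the midpoint has slope
-(Initial - Final)/(4 dx); it is the single per-complex tangent from which
the downstream temperature extrapolations start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .course_io import DissociationCourse

#: Fits below this coefficient of determination are flagged (not rejected).
R2_GATE = 0.99


class FitConvergenceError(RuntimeError):
    """The sigmoid fit did not converge; carries the initialization used."""


def boltzmann(x, initial: float, final: float, dcv50: float, dx: float):
    """The Boltzmann sigmoid evaluated at ``x`` (scalar or array)."""
    x = np.asarray(x, dtype=float)
    out = final + (initial - final) / (1.0 + np.exp((x - dcv50) / dx))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BoltzmannFit:
    """Fitted sigmoid parameters; one row of the course-characteristics table."""

    initial: float
    final: float
    dcv50: float
    dx: float
    r2: float = float("nan")
    covariance: np.ndarray | None = field(default=None, compare=False)
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise ValueError(f"dx must be > 0, got {self.dx}")
        if self.final > self.initial:
            raise ValueError(
                f"need final <= initial (decaying educt), got {self.initial} -> {self.final}"
            )
        if self.final < 0 or self.initial > 110.0:
            raise ValueError("plateaus must lie in [0, 110] %")

    @property
    def amplitude(self) -> float:
        return self.initial - self.final

    @property
    def midpoint_value(self) -> float:
        return 0.5 * (self.initial + self.final)

    @property
    def r2_ok(self) -> bool:
        return bool(self.r2 >= R2_GATE)

    @property
    def bse(self) -> np.ndarray | None:
        """Standard errors of (initial, final, dcv50, dx) from the covariance."""
        if self.covariance is None:
            return None
        return np.sqrt(np.diag(self.covariance))

    def value(self, x):
        return boltzmann(x, self.initial, self.final, self.dcv50, self.dx)


def boltzmann_value(fit: BoltzmannFit, x):
    """Sigmoid of a fit evaluated at ΔCV ``x`` (total function)."""
    return fit.value(x)


def midpoint_slope(fit: BoltzmannFit) -> float:
    """Analytic derivative at the midpoint, -(Initial - Final)/(4 dx), in %/V."""
    return -(fit.initial - fit.final) / (4.0 * fit.dx)


@dataclass(frozen=True)
class TangentLine:
    """The tangent to the sigmoid at its midpoint."""

    slope: float
    intercept: float
    anchor: tuple[float, float]

    def value(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    @property
    def x_intercept(self) -> float:
        return -self.intercept / self.slope


def tangent_line(fit: BoltzmannFit) -> TangentLine:
    """Line through (dcv50, midpoint) with the analytic midpoint slope."""
    slope = midpoint_slope(fit)
    anchor = (fit.dcv50, fit.midpoint_value)
    return TangentLine(slope=slope, intercept=anchor[1] - slope * anchor[0], anchor=anchor)


def _fit_arrays(
    x: np.ndarray, y: np.ndarray, sigma: np.ndarray | None = None
) -> BoltzmannFit:
    if x.size < 5:
        raise ValueError(f"need >= 5 points for a sigmoid fit, got {x.size}")
    span = float(np.ptp(y))
    if span < 5.0:
        raise ValueError(
            f"educt course spans only {span:.2f} % - no transition to fit"
        )
    trend = np.polyfit(x, y, 1)[0]
    if trend > 0 and y[np.argmax(x)] > y[np.argmin(x)]:
        raise ValueError(
            "educt course increases with ΔCV; an educt must decay "
            "(wrong species selected?)"
        )
    xrange = float(np.ptp(x))
    bounds = ([0.0, 0.0, float(np.min(x)) - xrange, 1e-9],
              [110.0, 110.0, float(np.max(x)) + xrange, xrange])
    p0 = np.clip(
        [
            float(np.max(y)),
            float(np.min(y)),
            float(x[np.argmin(np.abs(y - (np.max(y) + np.min(y)) / 2.0))]),
            xrange / 10.0,
        ],
        bounds[0],
        bounds[1],
    )
    try:
        popt, pcov = curve_fit(
            boltzmann, x, y, p0=p0, bounds=bounds, sigma=sigma, maxfev=20000
        )
    except RuntimeError as err:
        raise FitConvergenceError(
            f"Boltzmann fit did not converge (initialization p0={p0}, bounds={bounds}): {err}"
        ) from err
    resid = y - boltzmann(x, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    fit = BoltzmannFit(
        initial=float(popt[0]),
        final=float(popt[1]),
        dcv50=float(popt[2]),
        dx=float(popt[3]),
        r2=r2,
        covariance=pcov,
        n_points=int(x.size),
    )
    if not fit.r2_ok:
        warnings.warn(
            f"Boltzmann fit R² = {r2:.4f} below the {R2_GATE} quality gate", stacklevel=3
        )
    return fit


def fit_boltzmann(
    course: DissociationCourse,
    educt_id: str | None = None,
    weighted: bool = False,
) -> BoltzmannFit:
    """Least-squares Boltzmann fit of the (replicate-mean) educt course.

    Unweighted by default, matching practice of fitting mean courses; with
    ``weighted=True`` points are weighted by their replicate standard
    deviation where defined.
    """
    educt_id = educt_id or course.educt_id
    x, y, sd = course.species_course(educt_id)
    sigma = None
    if weighted:
        sigma = np.where(np.isfinite(sd) & (sd > 0), sd, np.nanmax(sd[np.isfinite(sd)]) if np.isfinite(sd).any() else 1.0)
    return _fit_arrays(x, y, sigma)


def fit_boltzmann_xy(x, y) -> BoltzmannFit:
    """Fit a sigmoid to raw (ΔCV, %) arrays (no course container required)."""
    return _fit_arrays(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
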