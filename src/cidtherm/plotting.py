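"""Course, Arrhenius and Gibbs-Helmholtz plots."""

from __future__ import annotations

import numpy as np

from .boltzmann import BoltzmannFit
from .course_io import DissociationCourse
from .thermo import TemperaturePoint, ThermoConfig, ThermoResult


def _ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_course(course: DissociationCourse, fit: BoltzmannFit | None = None, ax=None):
    """Normalized intensities vs ΔCV with sd bars and the fitted sigmoid."""
    ax = _ax(ax)
    for sp in course.species_ids:
        x, y, sd = course.species_course(sp)
        err = np.where(np.isfinite(sd), sd, 0.0)
        ax.errorbar(x, y, yerr=err, marker="o", linestyle="none", capsize=2, label=sp)
    if fit is not None:
        xs = np.linspace(course.dcv_grid.min(), course.dcv_grid.max(), 200)
        ax.plot(xs, fit.value(xs), "-", color="black", lw=1,
                label=f"Boltzmann fit (R²={fit.r2:.3f})")
    ax.set_xlabel("ΔCV [V]")
    ax.set_ylabel("normalized intensity [%]")
    ax.legend(fontsize="small")
    return ax


def plot_arrhenius(points: list[TemperaturePoint], result: ThermoResult,
                   cfg: ThermoConfig, ax=None):
    """ln k vs 1/T with the fitted line extended to ambient temperature."""
    ax = _ax(ax)
    inv_t = np.array([1.0 / p.t_eff for p in points])
    ln_k = np.log([p.k for p in points])
    ax.plot(inv_t, ln_k, "o", label="steep region")
    arr = result.arrhenius
    xs = np.linspace(inv_t.min(), 1.0 / cfg.t_amb, 100)
    ax.plot(xs, arr.line.intercept + arr.line.slope * xs, "--",
            label=f"extrapolation (Ea={arr.ea / 1000:.1f} kJ/mol)")
    ax.set_xlabel("1/T [1/K]")
    ax.set_ylabel("ln k")
    ax.legend(fontsize="small")
    return ax


def plot_gibbs_helmholtz(points: list[TemperaturePoint], result: ThermoResult,
                         cfg: ThermoConfig, ax=None):
    """ΔG vs T with the fitted line extended to ambient temperature."""
    from scipy.constants import R

    ax = _ax(ax)
    t = np.array([p.t_eff for p in points])
    dg = np.array([-R * p.t_eff * np.log(p.keq) for p in points]) / 1000.0
    ax.plot(t, dg, "o", label="steep region")
    gh = result.gibbs_helmholtz
    xs = np.linspace(cfg.t_amb, t.max(), 100)
    ax.plot(xs, gh.dh / 1000.0 - xs * gh.ds / 1000.0, "--",
            label=f"ΔG(T) = ΔH - TΔS (ΔH={gh.dh / 1000:.1f} kJ/mol)")
    ax.set_xlabel("T_eff [K]")
    ax.set_ylabel("ΔG [kJ/mol]")
    ax.legend(fontsize="small")
    return ax
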