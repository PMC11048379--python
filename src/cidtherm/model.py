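"""Model/results interface tying the pipeline stages together.

:class:`BreakdownModel` wraps one educt's dissociation course plus the ion
context and calibration; :meth:`BreakdownModel.fit` runs the Boltzmann fit,
the tangent construction and both temperature extrapolations and returns a
:class:`BreakdownResults` carrying estimates, uncertainties, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import boltzmann as bz
from . import thermo as th
from .composition import OligomerIon, Proteoform
from .course_io import DissociationCourse, ScanPeakTable, SpeciesAssignment, build_course

PARAM_NAMES = ("initial", "final", "dcv50", "dx")


class BreakdownModel:
    """Breakdown-curve model for one trimer educt ion.

    Parameters
    ----------
    course
        Normalized dissociation course (educt + products vs ΔCV).
    educt_ion
        The precursor ion; its mass, charge and atom number drive the
        effective-temperature conversion.
    proteoforms
        Registry resolving the ion's monomer masses and atom counts.
    config
        Calibration constants; defaults to :class:`~cidtherm.thermo.ThermoConfig`.
    """

    def __init__(
        self,
        course: DissociationCourse,
        educt_ion: OligomerIon,
        proteoforms: Mapping[str, Proteoform],
        config: th.ThermoConfig | None = None,
    ) -> None:
        if educt_ion.species.symbol != course.educt_id:
            raise ValueError(
                f"course educt {course.educt_id!r} does not match ion "
                f"{educt_ion.species.symbol!r}"
            )
        self.course = course
        self.educt_ion = educt_ion
        self.proteoforms = dict(proteoforms)
        self.config = config or th.ThermoConfig()

    @classmethod
    def from_peak_tables(
        cls,
        scans: Sequence[ScanPeakTable],
        assignments: Sequence[SpeciesAssignment],
        educt_ion: OligomerIon,
        proteoforms: Mapping[str, Proteoform],
        config: th.ThermoConfig | None = None,
    ) -> "BreakdownModel":
        course = build_course(scans, assignments, educt_ion.species.symbol)
        return cls(course, educt_ion, proteoforms, config)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        educt_ion: OligomerIon,
        proteoforms: Mapping[str, Proteoform],
        config: th.ThermoConfig | None = None,
    ) -> "BreakdownModel":
        """Build from a tidy frame with columns species, dcv, replicate, normalized."""
        educt = educt_ion.species.symbol
        species = list(dict.fromkeys(data["species"]))
        products = tuple(s for s in species if s != educt)
        course = DissociationCourse(educt, products, data.copy())
        return cls(course, educt_ion, proteoforms, config)

    def fit(self, weighted: bool = False, thermo: bool = True) -> "BreakdownResults":
        """Fit the sigmoid and (optionally) run both extrapolations."""
        fit = bz.fit_boltzmann(self.course, weighted=weighted)
        tangent = bz.tangent_line(fit)
        result = points = None
        if thermo:
            points = th.steep_region_points(fit, self.educt_ion, self.proteoforms, self.config)
            arr = th.arrhenius_extrapolate(points, self.config)
            gh = th.gibbs_helmholtz_extrapolate(points, self.config)
            result = th.ThermoResult.from_extrapolations(arr, gh, self.config)
        return BreakdownResults(self, fit, tangent, result, points)


@dataclass
class BreakdownResults:
    """Fitted breakdown-curve characteristics and extrapolated quantities."""

    model: BreakdownModel
    boltzmann: bz.BoltzmannFit
    tangent: bz.TangentLine
    thermo: th.ThermoResult | None = None
    points: list[th.TemperaturePoint] | None = field(default=None, repr=False)

    @property
    def params(self) -> pd.Series:
        f = self.boltzmann
        return pd.Series([f.initial, f.final, f.dcv50, f.dx], index=list(PARAM_NAMES))

    @property
    def bse(self) -> pd.Series:
        se = self.boltzmann.bse
        vals = se if se is not None else np.full(4, np.nan)
        return pd.Series(vals, index=list(PARAM_NAMES))

    @property
    def rsquared(self) -> float:
        return self.boltzmann.r2

    @property
    def slope(self) -> float:
        return self.tangent.slope

    def predict(self, dcv) -> np.ndarray:
        """Fitted educt intensity (%) at the given ΔCV values."""
        return np.asarray(self.boltzmann.value(dcv), dtype=float)

    def consistency(self, tol: float = 0.005) -> list[th.ConsistencyCheck]:
        if self.thermo is None:
            raise ValueError("no thermo extrapolation in this result")
        return th.consistency_report(self.thermo, self.model.config, tol=tol)

    def summary(self) -> str:
        """Human-readable report of the fit and the extrapolated quantities."""
        f = self.boltzmann
        se = self.bse
        cfg = self.model.config
        lines = [
            "Breakdown-curve analysis",
            "=" * 60,
            f"educt ion:        {self.model.educt_ion.symbol}",
            f"data points:      {f.n_points} ΔCV settings, "
            f"{self.model.course.n_replicates} replicate series",
            "",
            "Boltzmann sigmoid (normalized educt % vs ΔCV)",
            "-" * 60,
        ]
        for name, val in self.params.items():
            unit = "%" if name in ("initial", "final") else "V"
            err = f" ± {se[name]:.3f}" if np.isfinite(se[name]) else ""
            lines.append(f"  {name:<8} {val:10.2f}{err}  [{unit}]")
        lines += [
            f"  slope    {self.slope:10.2f}  [%/V] (midpoint tangent)",
            f"  R²       {f.r2:10.4f}" + ("" if f.r2_ok else "  ** below 0.99 gate **"),
        ]
        if self.thermo is not None:
            t = self.thermo
            lines += [
                "",
                f"Extrapolated apparent quantities at {t.t_amb:.0f} K",
                "-" * 60,
                f"  k#       {t.k_amb:10.3g}  [1/s]   "
                f"(Ea = {t.arrhenius.ea / 1000:.2f} kJ/mol, R² = {t.arrhenius.line.r2:.4f})",
                f"  KD#      {t.kd_amb:10.3g}  [-]",
                f"  ΔG#      {t.dg:10.2f}  [kJ/mol]",
                f"  ΔH#      {t.dh:10.2f}  [kJ/mol]  "
                f"(GH line R² = {t.gibbs_helmholtz.line.r2:.4f})",
                f"  TΔS#     {t.tds:10.2f}  [kJ/mol]",
                "",
                f"  residence time {cfg.residence_time:g} s; t0 {cfg.t0:g} K; "
                f"collision gas {cfg.gas_mass:g} Da × {cfg.n_collisions:g} collisions",
            ]
            for chk in self.consistency():
                status = "ok" if chk.ok else "FLAGGED"
                lines.append(
                    f"  check {chk.name}: Δ = {chk.deviation:+.3f} kJ/mol [{status}]"
                )
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_course(self, ax=None):
        from .plotting import plot_course

        return plot_course(self.model.course, fit=self.boltzmann, ax=ax)

    def plot_arrhenius(self, ax=None):
        from .plotting import plot_arrhenius

        return plot_arrhenius(self.points, self.thermo, self.model.config, ax=ax)

    def plot_gibbs_helmholtz(self, ax=None):
        from .plotting import plot_gibbs_helmholtz

        return plot_gibbs_helmholtz(self.points, self.thermo, self.model.config, ax=ax)
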