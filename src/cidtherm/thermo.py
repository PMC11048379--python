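"""Effective-temperature kinetics and quasi-thermodynamics of gas-phase dissociation.

The ΔCV axis of a breakdown course is mapped to an effective ion temperature,
each point of the fitted sigmoid's steep region yields a first-order rate
constant (from the educt survival over the collision-cell residence time) and
a quasi-equilibrium dissociation quotient, and two linear extrapolations to
ambient temperature produce the five apparent quantities:

* k#       - Arrhenius line of ln k vs 1/T, evaluated at T_amb,
* ΔH#, ΔS# - Gibbs-Helmholtz line of ΔG(T) = -R T ln K vs T
             (intercept ΔH#, slope -ΔS#),
* ΔG#      - ΔH# - T_amb ΔS#,
* KD#      - exp(-ΔG# / (R T_amb)), unitless.

The ΔCV -> temperature conversion is an *effective* instrument-dependent
calibration and is pluggable: the default partitions the centre-of-mass
collision energy of an effective number of ion/gas collisions over the ion's
3N - 6 vibrational modes.  Likewise the mole-fraction dissociation quotient is
referred to the 1 M standard state through an effective ion concentration; all
extrapolated quantities are "apparent" in the sense that they are conditional
on this calibration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.constants import R as R_GAS, e as E_CHARGE, k as K_BOLTZMANN

from .boltzmann import BoltzmannFit
from .composition import OligomerIon, Proteoform, atom_count as species_atom_count, species_mass


@dataclass(frozen=True)
class ThermoConfig:
    """Calibration constants of the temperature/rate/equilibrium conversions.

    t0
        Effective ion temperature at ΔCV = 0 in K (near-source conditions).
    t_amb
        Ambient temperature the extrapolations target, in K.
    gas_mass
        Collision gas molar mass in Da (argon by default).
    residence_time
        Ion transit time through the collision cell in s.  It scales every
        rate constant multiplicatively and cancels nowhere downstream.
    n_collisions
        Effective number of activating ion/neutral collisions across the
        cell.  A single centre-of-mass collision heats a ~1300-atom ion by
        ~1 K over the studied ΔCV range; hard-sphere mean-free-path
        arithmetic for a ~10 cm cell near 1e-2 mbar gives several hundred
        collisions, the default 500.
    ion_concentration / c_standard
        Effective ion concentration (mol/L) and standard-state concentration
        used to refer the mole-fraction dissociation quotient to the 1 M
        standard state; the default corresponds to ~1e7 ions/cm³.
    steep_lo, steep_hi, n_eval
        The steep region of the fitted sigmoid: points where the educt lies
        between ``steep_lo`` and ``steep_hi`` of the fitted amplitude,
        evaluated at ``n_eval`` evenly spaced ΔCV values on the fitted curve.
    temperature_model
        Optional replacement for the ΔCV -> temperature conversion with
        signature ``(dcv, z, ion_mass, n_atoms, cfg) -> K``.
    """

    t0: float = 300.0
    t_amb: float = 298.0
    gas_mass: float = 39.948
    residence_time: float = 1e-4
    n_collisions: float = 500.0
    ion_concentration: float = 1.7e-14
    c_standard: float = 1.0
    steep_lo: float = 0.1
    steep_hi: float = 0.9
    n_eval: int = 25
    temperature_model: Callable[..., float] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("t0", "t_amb", "gas_mass", "residence_time", "n_collisions",
                     "ion_concentration", "c_standard"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.steep_lo < self.steep_hi < 1.0:
            raise ValueError("need 0 < steep_lo < steep_hi < 1")

    @property
    def activity_scale(self) -> float:
        """Dimensionless factor converting a fraction quotient to standard state."""
        return self.ion_concentration / self.c_standard


def cv_to_temperature(
    dcv: float, z: int, ion_mass: float, n_atoms: int, cfg: ThermoConfig
) -> float:
    """Effective ion temperature in K at collision voltage difference ``dcv``.

    Default model: T = t0 + n_coll * z e ΔCV * m_gas/(m_gas + M_ion)
    / ((3N - 6) k_B) - the centre-of-mass collision energy of ``n_collisions``
    activating collisions equipartitioned over the vibrational modes.  Affine
    and strictly increasing in ΔCV.
    """
    if n_atoms < 2:
        raise ValueError(f"need >= 2 atoms for vibrational modes, got {n_atoms}")
    if dcv < 0:
        raise ValueError(f"dcv must be >= 0, got {dcv}")
    if cfg.temperature_model is not None:
        return float(cfg.temperature_model(dcv, z, ion_mass, n_atoms, cfg))
    dof = 3 * n_atoms - 6
    com_fraction = cfg.gas_mass / (cfg.gas_mass + ion_mass)
    energy = cfg.n_collisions * z * E_CHARGE * dcv * com_fraction
    return cfg.t0 + energy / (dof * K_BOLTZMANN)


def survival_to_rate(survival: float, cfg: ThermoConfig) -> float:
    """First-order rate constant k = -ln(survival)/residence_time in 1/s."""
    if not 0.0 < survival <= 1.0:
        raise ValueError(f"survival must be in (0, 1], got {survival}")
    return -math.log(survival) / cfg.residence_time


def equilibrium_quotient(trimer: float, dimer: float, monomer: float) -> float:
    """Unitless mole-fraction dissociation quotient (dimer * monomer / trimer).

    Fractions are on the 0-1 scale.  For hetero-trimers the two release
    channels are summed into the dimer and monomer fractions before calling
    this (the default channel treatment).
    """
    if trimer <= 0:
        raise ValueError(f"trimer fraction must be > 0, got {trimer}")
    if dimer < 0 or monomer < 0:
        raise ValueError("product fractions must be >= 0")
    return dimer * monomer / trimer


@dataclass(frozen=True)
class TemperaturePoint:
    """One steep-region point after the ΔCV -> temperature conversion."""

    dcv: float
    t_eff: float
    survival: float
    k: float
    keq: float


def steep_region_points(
    fit: BoltzmannFit, ion: OligomerIon, proteoforms: Mapping[str, Proteoform],
    cfg: ThermoConfig,
) -> list[TemperaturePoint]:
    """Evaluate the fitted sigmoid on its steep region and convert each point.

    The steep region is where the educt lies between ``steep_lo`` and
    ``steep_hi`` of the fitted amplitude (ΔCV in dcv50 ± dx·ln(hi/lo·...)),
    sampled at ``n_eval`` evenly spaced voltages.  Working on the fitted curve
    rather than raw points reflects that there is a single tangent - hence a
    single Arrhenius and a single Gibbs-Helmholtz line - per complex.
    """
    mass = species_mass(ion.species, proteoforms)
    n_atoms = species_atom_count(ion.species, proteoforms)
    # educt fraction f of amplitude: f = 1/(1+exp((x-x0)/dx)) => x = x0 + dx ln((1-f)/f)
    x_lo = fit.dcv50 + fit.dx * math.log((1 - cfg.steep_hi) / cfg.steep_hi)
    x_hi = fit.dcv50 + fit.dx * math.log((1 - cfg.steep_lo) / cfg.steep_lo)
    xs = np.linspace(max(x_lo, 0.0), x_hi, cfg.n_eval)
    points = []
    for x in xs:
        y = fit.value(float(x))          # educt in % of scan total
        s = y / 100.0
        if not 0.0 < s < 1.0:
            continue
        t_eff = cv_to_temperature(float(x), ion.z, mass, n_atoms, cfg)
        k = survival_to_rate(s, cfg)
        dimer = monomer = (1.0 - s) / 2.0   # one dimer + one monomer per event
        keq = equilibrium_quotient(s, dimer, monomer) * cfg.activity_scale
        points.append(TemperaturePoint(float(x), t_eff, s, k, keq))
    return points


@dataclass(frozen=True)
class LinearFit:
    """Slope/intercept/diagnostics of one extrapolation line."""

    slope: float
    intercept: float
    r2: float
    n_points: int


def _line(x: np.ndarray, y: np.ndarray) -> LinearFit:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return LinearFit(float(slope), float(intercept), r2, int(x.size))


@dataclass(frozen=True)
class ArrheniusFit:
    """ln k = ln A - Ea/(R T): activation energy, prefactor, k at T_amb."""

    ea: float            # J/mol
    ln_a: float
    k_amb: float         # 1/s
    line: LinearFit


def arrhenius_extrapolate(
    points: Sequence[TemperaturePoint], cfg: ThermoConfig
) -> ArrheniusFit:
    """Least-squares Arrhenius line through the steep-region points."""
    pts = [p for p in points if np.isfinite(p.k) and p.k > 0]
    dropped = len(points) - len(pts)
    if dropped:
        warnings.warn(f"excluded {dropped} points with non-finite rate constants", stacklevel=2)
    if len(pts) < 3:
        raise ValueError(f"need >= 3 points for the Arrhenius line, got {len(pts)}")
    inv_t = np.array([1.0 / p.t_eff for p in pts])
    ln_k = np.log([p.k for p in pts])
    if np.ptp(inv_t) == 0:
        raise ValueError("all points share one temperature - singular Arrhenius design")
    line = _line(inv_t, ln_k)
    ea = -line.slope * R_GAS
    ln_a = line.intercept
    k_amb = math.exp(ln_a + line.slope / cfg.t_amb)
    return ArrheniusFit(ea=ea, ln_a=ln_a, k_amb=k_amb, line=line)


@dataclass(frozen=True)
class GibbsHelmholtzFit:
    """ΔG(T) = ΔH - T ΔS line fitted to per-point -R T ln K values."""

    dh: float            # J/mol
    ds: float            # J/(mol K)
    dg_amb: float        # J/mol at t_amb
    line: LinearFit

    def tds(self, t: float) -> float:
        return t * self.ds


def gibbs_helmholtz_extrapolate(
    points: Sequence[TemperaturePoint], cfg: ThermoConfig
) -> GibbsHelmholtzFit:
    """Linear ΔG-vs-T fit over the steep region; extrapolated to T_amb."""
    pts = [p for p in points if p.keq > 0]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 points with positive quotient, got {len(pts)}")
    t = np.array([p.t_eff for p in pts])
    if np.ptp(t) == 0:
        raise ValueError("all points share one temperature - singular design")
    dg = np.array([-R_GAS * p.t_eff * math.log(p.keq) for p in pts])
    line = _line(t, dg)
    dh = line.intercept
    ds = -line.slope
    return GibbsHelmholtzFit(dh=dh, ds=ds, dg_amb=dh - cfg.t_amb * ds, line=line)


def delta_g_from_kd(kd: float, t: float) -> float:
    """ΔG = -R T ln KD, in kJ/mol."""
    if kd <= 0:
        raise ValueError(f"kd must be > 0, got {kd}")
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    return -R_GAS * t * math.log(kd) / 1000.0


@dataclass(frozen=True)
class ThermoResult:
    """The five extrapolated apparent quantities at ambient temperature.

    Energies in kJ/mol (internal computation is in J/mol), the rate constant
    in 1/s, the dissociation constant unitless.
    """

    k_amb: float
    kd_amb: float
    dg: float
    dh: float
    tds: float
    t_amb: float
    arrhenius: ArrheniusFit | None = None
    gibbs_helmholtz: GibbsHelmholtzFit | None = None

    @classmethod
    def from_extrapolations(
        cls, arr: ArrheniusFit, gh: GibbsHelmholtzFit, cfg: ThermoConfig
    ) -> "ThermoResult":
        dg_kj = gh.dg_amb / 1000.0
        kd = math.exp(-gh.dg_amb / (R_GAS * cfg.t_amb))
        return cls(
            k_amb=arr.k_amb,
            kd_amb=kd,
            dg=dg_kj,
            dh=gh.dh / 1000.0,
            tds=gh.tds(cfg.t_amb) / 1000.0,
            t_amb=cfg.t_amb,
            arrhenius=arr,
            gibbs_helmholtz=gh,
        )


@dataclass(frozen=True)
class ConsistencyCheck:
    name: str
    expected: float
    actual: float
    ok: bool

    @property
    def deviation(self) -> float:
        return self.actual - self.expected


def consistency_report(
    result: ThermoResult, cfg: ThermoConfig | None = None, tol: float = 0.005
) -> list[ConsistencyCheck]:
    """Internal identities between the five reported quantities.

    Checks ΔG = ΔH - TΔS and ΔG = -R T ln KD; deviations beyond ``tol``
    kJ/mol (default: half a unit of the 2-decimal reporting precision) are
    flagged.  Printed-table rows can disagree by exactly 0.01 kJ/mol through
    rounding; such rows are flagged, not hidden.
    """
    t = cfg.t_amb if cfg is not None else result.t_amb
    checks = []
    dg_from_hs = result.dh - result.tds
    checks.append(
        ConsistencyCheck(
            "dg == dh - tds", expected=result.dg, actual=dg_from_hs,
            ok=abs(dg_from_hs - result.dg) <= tol,
        )
    )
    dg_from_kd = delta_g_from_kd(result.kd_amb, t)
    checks.append(
        ConsistencyCheck(
            "dg == -R*T*ln(kd)", expected=result.dg, actual=dg_from_kd,
            ok=abs(dg_from_kd - result.dg) <= tol,
        )
    )
    return checks


def extrapolate(
    fit: BoltzmannFit,
    ion: OligomerIon,
    proteoforms: Mapping[str, Proteoform],
    cfg: ThermoConfig | None = None,
) -> ThermoResult:
    """Full steep-region -> Arrhenius + Gibbs-Helmholtz pipeline for one educt."""
    cfg = cfg or ThermoConfig()
    points = steep_region_points(fit, ion, proteoforms, cfg)
    arr = arrhenius_extrapolate(points, cfg)
    gh = gibbs_helmholtz_extrapolate(points, cfg)
    return ThermoResult.from_extrapolations(arr, gh, cfg)
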