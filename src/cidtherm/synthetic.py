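"""Synthetic dissociation experiments with known ground truth.

Two generators stand in for the instrument:

* :func:`simulate_course` draws an educt decay directly from Boltzmann sigmoid
  parameters (the study's observed course shapes), splits the complementary
  product rise across release channels, adds per-replicate Gaussian noise in
  absolute %, and renormalizes every scan to 100 %.
* :func:`simulate_thermo_course` drives the educt fraction through the
  thermodynamic forward model: a ΔG(T) = ΔH - TΔS line fixes the
  standard-state dissociation quotient at every effective temperature, which
  is inverted to the educt fraction.  Analyzing such a course with the same
  configuration must recover the generating (ΔH, ΔS) - the end-to-end
  parameter-recovery oracle.

Identical seeds give bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .boltzmann import boltzmann
from .composition import OligomerIon, Proteoform, dissociation_products, mz as ion_mz
from .course_io import DissociationCourse, ScanPeakTable
from .foldon import GRID_SERIES_1, GRID_SERIES_2, STUDY_COURSE_PARAMS, foldon_ions, foldon_proteoforms
from .thermo import ThermoConfig, cv_to_temperature

#: Default generating parameters of the thermodynamic forward model, chosen as
#: the scale the default configuration recovers from the canonical homo-trimer
#: course (transition centred on the study ΔCV grid): ΔH in J/mol, ΔS in
#: J/(mol K).
DEFAULT_THERMO_DH = 1.60e5
DEFAULT_THERMO_DS = -93.0


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth description of one simulated educt's experiment.

    ``channels`` lists the release channels as (dimer symbol, monomer symbol,
    weight); weights sum to 1 and the first channel's weight is the branching
    fraction.  Within a channel the dimer and monomer each receive half of the
    channel's product share (one dimer and one monomer ion per dissociation
    event, equal detection efficiency).
    """

    educt: str
    initial: float
    final: float
    dcv50: float
    dx: float
    channels: tuple[tuple[str, str, float], ...]
    grids: tuple[tuple[float, ...], ...] = (GRID_SERIES_1, GRID_SERIES_2)
    replicates: int = 2
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate")
        weights = [w for _, _, w in self.channels]
        if any(not 0.0 <= w <= 1.0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("channel weights must lie in [0, 1] and sum to 1")
        for grid in self.grids:
            if any(b <= a for a, b in zip(grid, grid[1:])):
                raise ValueError("ΔCV grids must be strictly increasing")

    @property
    def branching(self) -> float:
        return self.channels[0][2]

    @property
    def boltzmann_params(self) -> tuple[float, float, float, float]:
        return (self.initial, self.final, self.dcv50, self.dx)


def statistical_channels(
    educt_ion: OligomerIon, branching: float | None = None
) -> tuple[tuple[str, str, float], ...]:
    """Release channels of a trimer with statistical (per-subunit) weights.

    A trimer containing n copies of a proteoform releases it with weight n/3
    unless an explicit branching fraction (weight of the first channel) is
    given.
    """
    reaction = dissociation_products(educt_ion)
    stoich = Counter(educt_ion.species.stoichiometry)
    channels = []
    for dimer, monomer in reaction.product_pairs:
        released = monomer.stoichiometry[0]
        channels.append((dimer.symbol, monomer.symbol, stoich[released] / 3.0))
    if branching is not None:
        if len(channels) == 1:
            channels[0] = (*channels[0][:2], 1.0)
        elif len(channels) == 2:
            channels[0] = (*channels[0][:2], branching)
            channels[1] = (*channels[1][:2], 1.0 - branching)
        else:
            raise ValueError("explicit branching only defined for <= 2 channels")
    return tuple(channels)


def study_spec(
    educt: str,
    replicates: int | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    branching: float | None = None,
) -> SimulationSpec:
    """A :class:`SimulationSpec` reproducing the study conditions for one educt.

    Course parameters are the observed sigmoid characteristics; the doubly
    biotinylated hetero-trimer was acquired as a single series, the others as
    two series on the dense and sparse ΔCV grids.
    """
    params = STUDY_COURSE_PARAMS[educt]
    ions = foldon_ions()
    if replicates is None:
        replicates = 1 if educt == "F-bF-bF" else 2
    return SimulationSpec(
        educt=educt,
        initial=params[0], final=params[1], dcv50=params[2], dx=params[3],
        channels=statistical_channels(ions[educt], branching),
        replicates=replicates,
        noise_sd=noise_sd,
        seed=seed,
    )


def _scan_values(
    educt: str,
    educt_pct: float,
    channels: Sequence[tuple[str, str, float]],
) -> dict[str, float]:
    values = {educt: educt_pct}
    remainder = 100.0 - educt_pct
    for dimer, monomer, w in channels:
        values[dimer] = values.get(dimer, 0.0) + remainder * w / 2.0
        values[monomer] = values.get(monomer, 0.0) + remainder * w / 2.0
    return values


def _noisy_scan(
    values: dict[str, float], noise_sd: float, rng: np.random.Generator
) -> dict[str, float]:
    # additive Gaussian noise in absolute %, truncated at 0, then renormalized
    for _ in range(100):
        noisy = {
            k: max(0.0, v + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
            for k, v in values.items()
        }
        total = sum(noisy.values())
        if total > 0:
            return {k: 100.0 * v / total for k, v in noisy.items()}
        warnings.warn("noise drove a scan total to zero; resampling", stacklevel=3)
    raise RuntimeError("could not draw a scan with positive total intensity")


def _assemble_course(
    educt: str,
    channels: Sequence[tuple[str, str, float]],
    educt_pct_of: Callable[[float], float],
    grids: Sequence[Sequence[float]],
    replicates: int,
    noise_sd: float,
    seed: int,
) -> DissociationCourse:
    rng = np.random.default_rng(seed)
    rows = []
    species_order: dict[str, None] = {}
    for r in range(replicates):
        series = f"series-{r + 1}"
        grid = grids[r % len(grids)]
        for dcv in grid:
            values = _scan_values(educt, educt_pct_of(float(dcv)), channels)
            scan = _noisy_scan(values, noise_sd, rng)
            for sp, v in scan.items():
                species_order.setdefault(sp, None)
                rows.append((sp, float(dcv), series, v))
    df = pd.DataFrame(rows, columns=["species", "dcv", "replicate", "normalized"])
    df = df.sort_values(["species", "dcv", "replicate"], ignore_index=True)
    products = tuple(s for s in species_order if s != educt)
    return DissociationCourse(educt, products, df)


def simulate_course(spec: SimulationSpec) -> tuple[DissociationCourse, dict]:
    """Simulate one educt's dissociation course from sigmoid parameters.

    Returns the course together with a ground-truth record (the generating
    parameters, exact per-grid noise-free educt values, and the branching).
    """
    p = spec.boltzmann_params

    def educt_pct(dcv: float) -> float:
        return float(boltzmann(dcv, *p))

    course = _assemble_course(
        spec.educt, spec.channels, educt_pct, spec.grids,
        spec.replicates, spec.noise_sd, spec.seed,
    )
    truth = {
        "educt": spec.educt,
        "initial": spec.initial,
        "final": spec.final,
        "dcv50": spec.dcv50,
        "dx": spec.dx,
        "branching": spec.branching,
        "channels": [list(c) for c in spec.channels],
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return course, truth


def fraction_from_keq(keq: float, activity_scale: float) -> float:
    """Invert the standard-state quotient to the educt fraction.

    With products split equally, q = ((1-s)/2)²/s and keq = q * scale; the
    educt fraction is the root of s² - (2 + 4q)s + 1 = 0 in (0, 1):
    s = 1 + 2q - 2 sqrt(q² + q).
    """
    q = keq / activity_scale
    return 1.0 + 2.0 * q - 2.0 * math.sqrt(q * q + q)


def simulate_thermo_course(
    educt_ion: OligomerIon,
    proteoforms: Mapping[str, Proteoform] | None = None,
    dh: float = DEFAULT_THERMO_DH,
    ds: float = DEFAULT_THERMO_DS,
    cfg: ThermoConfig | None = None,
    grids: Sequence[Sequence[float]] = (GRID_SERIES_1, GRID_SERIES_2),
    replicates: int = 2,
    noise_sd: float = 1.0,
    seed: int = 0,
    branching: float | None = None,
) -> tuple[DissociationCourse, dict]:
    """Simulate a course whose quotient follows ΔG(T) = ΔH - T ΔS exactly.

    ``dh`` in J/mol, ``ds`` in J/(mol K).  The educt fraction at each ΔCV is
    obtained by converting ΔCV to the effective temperature, evaluating
    K(T) = exp(-(ΔH - TΔS)/(R T)) and inverting the quotient relation.
    """
    from scipy.constants import R as R_GAS

    cfg = cfg or ThermoConfig()
    proteoforms = proteoforms or foldon_proteoforms()
    from .composition import atom_count as species_atom_count, species_mass

    mass = species_mass(educt_ion.species, proteoforms)
    n_atoms = species_atom_count(educt_ion.species, proteoforms)

    def educt_pct(dcv: float) -> float:
        t = cv_to_temperature(dcv, educt_ion.z, mass, n_atoms, cfg)
        keq = math.exp(-(dh - t * ds) / (R_GAS * t))
        return 100.0 * fraction_from_keq(keq, cfg.activity_scale)

    channels = statistical_channels(educt_ion, branching)
    course = _assemble_course(
        educt_ion.species.symbol, channels, educt_pct, grids,
        replicates, noise_sd, seed,
    )
    truth = {
        "educt": educt_ion.species.symbol,
        "dh": dh,
        "ds": ds,
        "dg_amb": dh - cfg.t_amb * ds,
        "tds_amb": cfg.t_amb * ds,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return course, truth


def emit_peak_tables(
    course: DissociationCourse,
    ions: Mapping[str, OligomerIon],
    proteoforms: Mapping[str, Proteoform],
    window_mz: float = 0.5,
    scale: float = 1000.0,
) -> list[ScanPeakTable]:
    """One peak per species per scan at its calculated m/z.

    Intensities are proportional to the normalized fractions, so rebuilding a
    course from the tables reproduces the input course to numerical identity.
    Species whose calculated m/z values are closer than twice the matching
    window collide and raise an error.
    """
    species = list(course.species_ids)
    centers = {}
    for sp in species:
        if sp not in ions:
            raise KeyError(f"no ion definition for species {sp!r}")
        centers[sp] = ion_mz(ions[sp], proteoforms)
    ordered = sorted(centers.items(), key=lambda kv: kv[1])
    for (sa, ma), (sb, mb) in zip(ordered[:-1], ordered[1:]):
        if mb - ma < 2 * window_mz:
            raise ValueError(
                f"m/z collision between {sa} ({ma:.2f}) and {sb} ({mb:.2f}) "
                f"within ±{window_mz} window"
            )
    tables = []
    for (rep, dcv), sub in course.data.groupby(["replicate", "dcv"], sort=True):
        vals = dict(zip(sub["species"], sub["normalized"]))
        peaks = [(centers[sp], vals.get(sp, 0.0) * scale / 100.0) for sp in species]
        tables.append(ScanPeakTable(str(rep), float(dcv), peaks))
    return tables
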