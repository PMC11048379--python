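"""Per-voltage peak tables -> normalized dissociation courses.

Each mass spectrum recorded at one collision cell voltage difference (ΔCV)
becomes a :class:`ScanPeakTable`.  Expected ions are matched by an m/z window,
signal *heights* are extracted (maximum peak height inside the window), per-scan
intensities are normalized so every scan sums to 100 %, and replicate series
are merged into a tidy :class:`DissociationCourse` with per-point mean and
standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import OligomerIon, Proteoform, mz as ion_mz

#: Normalized per-scan species fractions must sum to 100 within this (absolute %).
SUM_TOL = 0.01


@dataclass
class ScanPeakTable:
    """Centroided peak list (m/z, height) of one scan at one ΔCV setting."""

    series_id: str
    dcv: float
    peaks: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        if self.dcv < 0:
            raise ValueError(f"dcv must be >= 0, got {self.dcv}")
        pk = sorted((float(m), float(i)) for m, i in self.peaks)
        if any(i < 0 for _, i in pk):
            raise ValueError("peak intensities must be >= 0")
        self.peaks = pk

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])


@dataclass(frozen=True)
class SpeciesAssignment:
    """An expected ion and the m/z window used to pick up its signal.

    ``window_mz`` is a half-width in Da/charge (default 0.5; charge-reduced
    foldon species are >100 m/z apart); ``window_ppm`` overrides it in ppm.
    ``measured_mz`` recenters the window on an experimentally observed value.
    ``satellite_of`` marks the assignment as a satellite (e.g. oxidation or
    sodiation) whose intensity is summed into the named parent species.
    """

    ion: OligomerIon
    center_mz: float
    window_mz: float = 0.5
    window_ppm: float | None = None
    measured_mz: float | None = None
    satellite_of: str | None = None

    def __post_init__(self) -> None:
        if self.window_ppm is not None:
            if self.window_ppm <= 0:
                raise ValueError("window_ppm must be > 0")
        elif self.window_mz <= 0:
            raise ValueError("window_mz must be > 0")

    @property
    def center(self) -> float:
        return self.measured_mz if self.measured_mz is not None else self.center_mz

    @property
    def half_width(self) -> float:
        if self.window_ppm is not None:
            return self.center * self.window_ppm * 1e-6
        return self.window_mz

    @property
    def species_id(self) -> str:
        return self.satellite_of or self.ion.species.symbol


def make_assignments(
    ions: Iterable[OligomerIon],
    proteoforms: Mapping[str, Proteoform],
    window_mz: float = 0.5,
    window_ppm: float | None = None,
) -> list[SpeciesAssignment]:
    """Build assignments for a set of ions at their calculated m/z."""
    return [
        SpeciesAssignment(ion, ion_mz(ion, proteoforms), window_mz=window_mz, window_ppm=window_ppm)
        for ion in ions
    ]


def extract_intensity(scan: ScanPeakTable, assignment: SpeciesAssignment) -> float:
    """Maximum peak height within the assignment window; 0 if the window is empty."""
    lo = assignment.center - assignment.half_width
    hi = assignment.center + assignment.half_width
    best = 0.0
    for m, i in scan.peaks:
        if lo <= m <= hi:
            best = max(best, i)
        elif m > hi:
            break
    return best


def _assign_scan(
    scan: ScanPeakTable, assignments: Sequence[SpeciesAssignment]
) -> dict[str, float]:
    """Per-species intensities with deterministic overlap resolution.

    When two assignment windows overlap, each peak in the overlap is credited
    to the assignment with the nearest window center (a warning is emitted).
    Satellite assignments are summed into their parent species.
    """
    centers = np.array([a.center for a in assignments])
    widths = np.array([a.half_width for a in assignments])
    order = np.argsort(centers)
    for i, j in zip(order[:-1], order[1:]):
        if centers[j] - centers[i] < widths[i] + widths[j]:
            warnings.warn(
                f"m/z windows of {assignments[i].ion.symbol} and {assignments[j].ion.symbol} "
                "overlap; peaks in the overlap are credited to the nearest window center",
                stacklevel=3,
            )
    best = np.zeros(len(assignments))
    for m, inten in scan.peaks:
        inside = np.nonzero(np.abs(m - centers) <= widths)[0]
        if inside.size == 0:
            continue
        k = inside[np.argmin(np.abs(m - centers[inside]))]
        best[k] = max(best[k], inten)
    out: dict[str, float] = {}
    for a, v in zip(assignments, best):
        out[a.species_id] = out.get(a.species_id, 0.0) + v
    return out


def normalize_scan(intensities: Mapping[str, float]) -> dict[str, float]:
    """Scale intensities so the scan total is 100 %."""
    total = float(sum(intensities.values()))
    if total <= 0:
        raise ValueError("cannot normalize an all-zero scan")
    return {k: 100.0 * v / total for k, v in intensities.items()}


@dataclass
class DissociationCourse:
    """Normalized educt/product intensities vs ΔCV, with replicates.

    ``data`` is tidy: one row per (species, dcv, replicate) holding the
    normalized intensity in % of the per-scan total.  Every scan sums to
    100 ± 0.01 %.  Standard deviations are defined only where the replicate
    count is >= 2.
    """

    educt_id: str
    product_ids: tuple[str, ...]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"species", "dcv", "replicate", "normalized"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"course data lacks columns {sorted(missing)}")
        self.product_ids = tuple(self.product_ids)
        sums = self.data.groupby(["replicate", "dcv"])["normalized"].sum()
        bad = sums[(sums - 100.0).abs() > SUM_TOL]
        if not bad.empty:
            rep, dcv = bad.index[0]
            raise ValueError(
                f"scan (replicate {rep!r}, dcv {dcv}) sums to {bad.iloc[0]:.4f} %, not 100 %"
            )

    @property
    def species_ids(self) -> tuple[str, ...]:
        return (self.educt_id, *self.product_ids)

    @property
    def dcv_grid(self) -> np.ndarray:
        return np.sort(self.data["dcv"].unique())

    @property
    def n_replicates(self) -> int:
        return self.data["replicate"].nunique()

    def stats(self) -> pd.DataFrame:
        """Per (species, dcv): mean, sd (NaN where n < 2) and replicate count."""
        g = self.data.groupby(["species", "dcv"])["normalized"]
        out = g.agg(mean="mean", sd="std", n="count").reset_index()
        return out.sort_values(["species", "dcv"], ignore_index=True)

    def species_course(self, species_id: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(dcv, mean, sd) arrays for one species, sorted by ΔCV."""
        st = self.stats()
        sub = st[st["species"] == species_id].sort_values("dcv")
        if sub.empty:
            raise KeyError(f"species {species_id!r} not in course")
        return sub["dcv"].to_numpy(float), sub["mean"].to_numpy(float), sub["sd"].to_numpy(float)

    def educt_course(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.species_course(self.educt_id)

    def to_csv(self, path: str | Path) -> None:
        """Tidy CSV: species, dcv, replicate, normalized, mean, sd."""
        st = self.stats().set_index(["species", "dcv"])
        df = self.data.copy().sort_values(["species", "dcv", "replicate"], ignore_index=True)
        keys = pd.MultiIndex.from_frame(df[["species", "dcv"]])
        df["mean"] = st["mean"].reindex(keys).to_numpy()
        df["sd"] = st["sd"].reindex(keys).to_numpy()
        df.insert(0, "educt", [self.educt_id] * len(df))
        df.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DissociationCourse":
        df = pd.read_csv(path)
        educt = str(df["educt"].iloc[0]) if "educt" in df.columns else None
        species = list(dict.fromkeys(df["species"]))
        if educt is None:
            educt = species[0]
        products = tuple(s for s in species if s != educt)
        return cls(educt, products, df[["species", "dcv", "replicate", "normalized"]].copy())


def build_course(
    scans: Iterable[ScanPeakTable],
    assignments: Sequence[SpeciesAssignment],
    educt_id: str,
    min_dcv_points: int = 4,
) -> DissociationCourse:
    """Assemble a dissociation course from raw scans.

    Each scan is normalized on its own before replicates are merged, so a ΔCV
    present in only one series is kept (its sd is then undefined).  Duplicate
    (series, ΔCV) pairs are an error.
    """
    scans = list(scans)
    seen: set[tuple[str, float]] = set()
    rows = []
    for scan in scans:
        key = (scan.series_id, scan.dcv)
        if key in seen:
            raise ValueError(f"duplicate scan for series {scan.series_id!r} at dcv {scan.dcv}")
        seen.add(key)
        intensities = _assign_scan(scan, assignments)
        try:
            normalized = normalize_scan(intensities)
        except ValueError:
            raise ValueError(
                f"all-zero scan at dcv {scan.dcv} (series {scan.series_id!r})"
            ) from None
        for species_id, value in normalized.items():
            rows.append((species_id, scan.dcv, scan.series_id, value))
    df = pd.DataFrame(rows, columns=["species", "dcv", "replicate", "normalized"])
    if df.empty or df["dcv"].nunique() < min_dcv_points:
        raise ValueError(f"need >= {min_dcv_points} distinct ΔCV settings")
    species_ids = list(dict.fromkeys(a.species_id for a in assignments))
    if educt_id not in species_ids:
        raise KeyError(f"educt {educt_id!r} has no assignment")
    products = tuple(s for s in species_ids if s != educt_id)
    # deterministic row order regardless of scan input order
    df = df.sort_values(["species", "dcv", "replicate"], ignore_index=True)
    return DissociationCourse(educt_id, products, df)


# ---------------------------------------------------------------------------
# plain-text I/O for peak tables


def write_peak_tables_csv(scans: Iterable[ScanPeakTable], path: str | Path) -> None:
    """Long-format CSV: series_id, dcv, mz, intensity."""
    rows = [
        (s.series_id, s.dcv, m, i)
        for s in scans
        for m, i in s.peaks
    ]
    pd.DataFrame(rows, columns=["series_id", "dcv", "mz", "intensity"]).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_peak_tables_csv(path: str | Path) -> list[ScanPeakTable]:
    df = pd.read_csv(path)
    out = []
    for (series, dcv), sub in df.groupby(["series_id", "dcv"], sort=True):
        out.append(
            ScanPeakTable(str(series), float(dcv), list(zip(sub["mz"], sub["intensity"])))
        )
    return out


def read_mzml_peaks(
    path: str | Path,
    dcv_of_scan: Sequence[float],
    series_id: str = "series-1",
) -> list[ScanPeakTable]:
    """Centroided mzML ingestion: the i-th spectrum is assigned ``dcv_of_scan[i]``.

    Profile-mode processing is out of scope; spectra must already be centroided.
    """
    from pyteomics import mzml

    out = []
    with mzml.read(str(path)) as reader:
        for i, spec in enumerate(reader):
            if i >= len(dcv_of_scan):
                break
            peaks = list(zip(spec["m/z array"], spec["intensity array"]))
            out.append(ScanPeakTable(series_id, float(dcv_of_scan[i]), peaks))
    return out
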