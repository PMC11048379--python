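"""Report tables mirroring the standard presentation layouts.

All numeric rounding (2 decimals for %, V and kJ/mol; 3 significant figures
for rate and equilibrium constants) happens here, at serialization - never
inside the computation modules.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .boltzmann import BoltzmannFit, midpoint_slope
from .composition import OligomerIon, Proteoform, atom_count, mz
from .thermo import ConsistencyCheck, ThermoResult


def _sig3(x: float) -> str:
    return f"{x:.3g}"


def species_table(
    ions: Sequence[OligomerIon] | Mapping[str, OligomerIon],
    proteoforms: Mapping[str, Proteoform],
) -> pd.DataFrame:
    """Molecular-information table: symbol, m/z (calcd), z, atom number."""
    if isinstance(ions, Mapping):
        ions = list(ions.values())
    rows = [
        {
            "symbol": ion.species.symbol,
            "mz_calcd": round(mz(ion, proteoforms), 2),
            "z": f"{ion.z}+",
            "atom_no": atom_count(ion.species, proteoforms),
        }
        for ion in ions
    ]
    return pd.DataFrame(rows)


def boltzmann_table(fits: Mapping[str, BoltzmannFit]) -> pd.DataFrame:
    """Course-characteristics table: plateaus, midpoint, width, slope, R²."""
    rows = []
    for i, (symbol, fit) in enumerate(fits.items(), start=1):
        rows.append(
            {
                "no": i,
                "complex": symbol,
                "initial_pct": round(fit.initial, 2),
                "final_pct": round(fit.final, 2),
                "dcv50_v": round(fit.dcv50, 2),
                "dx_v": round(fit.dx, 2),
                "slope_pct_per_v": round(midpoint_slope(fit), 2),
                "r2": round(fit.r2, 3),
                "r2_ok": fit.r2_ok,
            }
        )
    return pd.DataFrame(rows)


def thermo_table(results: Mapping[str, ThermoResult]) -> pd.DataFrame:
    """Apparent kinetic/quasi-thermodynamic table (k#, KD#, ΔG#, ΔH#, TΔS#)."""
    rows = []
    for i, (symbol, res) in enumerate(results.items(), start=1):
        rows.append(
            {
                "no": i,
                "complex": symbol,
                "k_per_s": _sig3(res.k_amb),
                "kd": _sig3(res.kd_amb),
                "dg_kj_mol": round(res.dg, 2),
                "dh_kj_mol": round(res.dh, 2),
                "tds_kj_mol": round(res.tds, 2),
                "arrhenius_r2": round(res.arrhenius.line.r2, 4) if res.arrhenius else float("nan"),
                "gh_r2": round(res.gibbs_helmholtz.line.r2, 4) if res.gibbs_helmholtz else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def consistency_table(checks: Mapping[str, Sequence[ConsistencyCheck]]) -> pd.DataFrame:
    rows = []
    for symbol, chks in checks.items():
        for c in chks:
            rows.append(
                {
                    "complex": symbol,
                    "check": c.name,
                    "expected_kj_mol": round(c.expected, 3),
                    "actual_kj_mol": round(c.actual, 3),
                    "deviation_kj_mol": round(c.deviation, 3),
                    "ok": c.ok,
                }
            )
    return pd.DataFrame(rows)
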