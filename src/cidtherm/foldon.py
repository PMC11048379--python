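"""The T4 fibritin foldon (T4Ff) model system used throughout the examples.

T4Ff is a 27-residue miniprotein that spontaneously trimerizes.  The working
system mixes unmodified foldon ("F", elemental composition C142 H214 N36 O41)
with an N-terminally biotinylated variant carrying two 8-amino-3,6-dioxa-
octanoic acid spacers ("bF").  The vendor-declared biotinylated-foldon formula
is not self-consistent with its declared monoisotopic mass and atom number, so
bF is defined here by its declared monoisotopic mass (3594.82 Da) and declared
atom count (505); user-supplied formulas are never silently corrected.

Mixing F and bF gives four trimers (F-F-F ... bF-bF-bF, observed at 5+),
three dimers (3+) and two monomers (2+).
"""

from __future__ import annotations

from .composition import ElementalComposition, OligomerIon, OligomerSpecies, Proteoform

#: Sigmoid course parameters (initial %, final %, dcv50 V, dx V) of the four
#: trimer educts, used as the synthetic generator's study conditions.
STUDY_COURSE_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "F-F-F": (98.78, 0.00, 17.03, 1.70),
    "F-F-bF": (99.64, 0.00, 16.93, 2.32),
    "F-bF-bF": (100.00, 0.00, 20.51, 2.95),
    "bF-bF-bF": (100.00, 0.26, 19.57, 1.84),
}

#: ΔCV grids (V) of the two acquisition series; the second is a sparse subset.
GRID_SERIES_1 = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 15.0, 18.0, 22.0, 26.0, 30.0, 35.0, 40.0, 45.0, 50.0, 55.0)
GRID_SERIES_2 = (4.0, 8.0, 12.0, 18.0, 26.0, 35.0, 45.0, 55.0)

#: Charge states at which each oligomer role is observed.
ROLE_CHARGES = {"trimer": 5, "dimer": 3, "monomer": 2}


def foldon_proteoforms() -> dict[str, Proteoform]:
    """The F/bF proteoform registry (insertion order = canonical symbol order)."""
    f = Proteoform(
        id="F",
        name="T4 fibritin foldon",
        composition=ElementalComposition.from_formula("C142H214N36O41"),
    )
    bf = Proteoform(
        id="bF",
        name="biotinylated T4 fibritin foldon",
        monoiso_mass=3594.82,
        atom_count=505,
    )
    return {f.id: f, bf.id: bf}


def foldon_species() -> list[OligomerSpecies]:
    """The nine oligomer species of the F/bF mixture (4 trimers, 3 dimers, 2 monomers)."""
    from .composition import enumerate_mixture_species

    pf = foldon_proteoforms()
    return enumerate_mixture_species(pf["F"], pf["bF"])


def foldon_ions() -> dict[str, OligomerIon]:
    """Observed ions, keyed by species symbol: trimers 5+, dimers 3+, monomers 2+."""
    return {
        sp.symbol: OligomerIon(sp, ROLE_CHARGES[sp.role])
        for sp in foldon_species()
    }


def trimer_ion(symbol: str) -> OligomerIon:
    ions = foldon_ions()
    ion = ions[symbol]
    if ion.species.role != "trimer":
        raise ValueError(f"{symbol!r} is not a trimer")
    return ion
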