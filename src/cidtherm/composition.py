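"""Mass, m/z and atom-count calculus for proteoform oligomer ions.

Non-covalent oligomers (here: trimers of the T4 fibritin foldon miniprotein
and its biotinylated variant) are observed in native ESI mass spectra as
multiply protonated pseudo-molecular ions.  This module computes monoisotopic
masses from elemental compositions, m/z values for protonated oligomer ions,
total atom numbers (needed for the vibrational degree-of-freedom count in the
effective-temperature conversion), and enumerates the dissociation reactions
of trimeric educts into dimer/monomer product pairs.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pyteomics.mass import nist_mass
from scipy.constants import physical_constants

#: Mass of a proton in Da; protonation (not H-atom addition) charges the ions.
PROTON_MASS = physical_constants["proton mass in u"][0]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

ROLE_BY_SIZE = {1: "monomer", 2: "dimer", 3: "trimer"}

#: Default charge partition of a dissociating trimer educt: (dimer z, monomer z).
DEFAULT_CHARGE_SPLIT = {5: (3, 2), 6: (4, 2)}


class UnknownElementError(ValueError):
    """An element symbol with no tabulated monoisotopic mass."""


def _element_mass(symbol: str) -> float:
    try:
        return nist_mass[symbol][0][0]
    except KeyError:
        raise UnknownElementError(f"unknown element symbol: {symbol!r}") from None


@dataclass(frozen=True)
class ElementalComposition:
    """An element -> count mapping, e.g. C142 H214 N36 O41 for the foldon monomer."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for el, n in dict(self.counts).items():
            if n != int(n) or n < 0:
                raise ValueError(f"count for {el!r} must be a non-negative integer, got {n!r}")
            _element_mass(el)  # validate symbol eagerly
            if n > 0:
                clean[el] = int(n)
        if not clean:
            raise ValueError("composition must contain at least one atom")
        object.__setattr__(self, "counts", clean)

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-style formula string such as ``"C142H214N36O41"``."""
        counts: Counter = Counter()
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
            counts[m.group(1)] += int(m.group(2) or 1)
            pos = m.end()
        if pos != len(formula) or not counts:
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(counts)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def monoisotopic_mass(self) -> float:
        return sum(n * _element_mass(el) for el, n in self.counts.items())

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(Counter(self.counts) + Counter(other.counts))

    def formula(self) -> str:
        return "".join(f"{el}{n}" for el, n in sorted(self.counts.items()))


def monoisotopic_mass(composition: ElementalComposition) -> float:
    """Monoisotopic mass in Da of an elemental composition."""
    return composition.monoisotopic_mass()


@dataclass(frozen=True)
class Proteoform:
    """A monomer building block (e.g. foldon "F" or biotinylated foldon "bF").

    Either an elemental composition or a declared monoisotopic mass must be
    given.  When both are present the composition-derived mass is used for all
    downstream calculations (declared, table-printed masses carry rounding
    error) and a disagreement beyond 0.02 Da triggers a warning.  A declared
    ``atom_count`` is honoured only when no composition is available; it is
    never used to "correct" a user-supplied formula.
    """

    id: str
    name: str = ""
    composition: ElementalComposition | None = None
    monoiso_mass: float | None = None
    avg_mass: float | None = None
    atom_count: int | None = None

    def __post_init__(self) -> None:
        if self.composition is None and self.monoiso_mass is None:
            raise ValueError(f"proteoform {self.id!r}: need a composition or a monoisotopic mass")
        if self.monoiso_mass is not None and self.monoiso_mass <= 0:
            raise ValueError(f"proteoform {self.id!r}: monoisotopic mass must be positive")
        if self.composition is not None and self.monoiso_mass is not None:
            delta = abs(self.composition.monoisotopic_mass() - self.monoiso_mass)
            if delta > 0.02:
                warnings.warn(
                    f"proteoform {self.id!r}: composition-derived mass "
                    f"{self.composition.monoisotopic_mass():.4f} Da differs from the "
                    f"declared {self.monoiso_mass:.4f} Da by {delta:.4f} Da; "
                    "the composition-derived value will be used",
                    stacklevel=2,
                )
        if self.composition is not None and self.atom_count is not None:
            if self.composition.n_atoms != self.atom_count:
                warnings.warn(
                    f"proteoform {self.id!r}: composition has {self.composition.n_atoms} atoms "
                    f"but {self.atom_count} were declared; the composition count will be used",
                    stacklevel=2,
                )

    @property
    def mass(self) -> float:
        if self.composition is not None:
            return self.composition.monoisotopic_mass()
        assert self.monoiso_mass is not None
        return self.monoiso_mass

    @property
    def n_atoms(self) -> int:
        if self.composition is not None:
            return self.composition.n_atoms
        if self.atom_count is not None:
            return self.atom_count
        raise ValueError(f"proteoform {self.id!r} has neither composition nor declared atom count")


def _canonical_ids(ids: Iterable[str], order: Sequence[str] | None = None) -> tuple[str, ...]:
    # Unmodified (shorter-label) proteoform first: "F" before "bF".  An explicit
    # registry order overrides the lexical default.
    if order is not None:
        rank = {pid: i for i, pid in enumerate(order)}
        return tuple(sorted(ids, key=lambda i: (rank.get(i, len(rank)), i)))
    return tuple(sorted(ids, key=lambda i: (len(i), i)))


@dataclass(frozen=True)
class OligomerSpecies:
    """A stoichiometry of proteoform ids (1-3 subunits) with a canonical symbol."""

    stoichiometry: tuple[str, ...]
    symbol: str = ""
    role: str = ""

    def __post_init__(self) -> None:
        stoich = tuple(self.stoichiometry)
        if not 1 <= len(stoich) <= 3:
            raise ValueError(f"stoichiometry size must be 1-3, got {len(stoich)}")
        role = ROLE_BY_SIZE[len(stoich)]
        if self.role and self.role != role:
            raise ValueError(f"role {self.role!r} inconsistent with {len(stoich)} subunits")
        object.__setattr__(self, "stoichiometry", stoich)
        object.__setattr__(self, "role", role)
        if not self.symbol:
            object.__setattr__(self, "symbol", "-".join(stoich))

    @classmethod
    def from_ids(cls, ids: Iterable[str], order: Sequence[str] | None = None) -> "OligomerSpecies":
        return cls(_canonical_ids(ids, order))

    @property
    def size(self) -> int:
        return len(self.stoichiometry)


@dataclass(frozen=True)
class OligomerIon:
    """A protonated oligomer species at charge state ``z``."""

    species: OligomerSpecies
    z: int

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError(f"charge must be >= 1, got {self.z}")

    @property
    def symbol(self) -> str:
        return f"{self.species.symbol} {self.z}+"


def _resolve(proteoforms: Mapping[str, Proteoform], pid: str) -> Proteoform:
    try:
        return proteoforms[pid]
    except KeyError:
        raise KeyError(f"unknown proteoform id {pid!r}") from None


def species_mass(species: OligomerSpecies, proteoforms: Mapping[str, Proteoform]) -> float:
    """Neutral monoisotopic mass of an oligomer species in Da."""
    return sum(_resolve(proteoforms, pid).mass for pid in species.stoichiometry)


def atom_count(species: OligomerSpecies, proteoforms: Mapping[str, Proteoform]) -> int:
    """Total atom number over all monomers (added protons excluded)."""
    return sum(_resolve(proteoforms, pid).n_atoms for pid in species.stoichiometry)


def mz(ion: OligomerIon, proteoforms: Mapping[str, Proteoform]) -> float:
    """m/z of a protonated oligomer ion: (M + z*m_p)/z, full precision."""
    neutral = species_mass(ion.species, proteoforms)
    return (neutral + ion.z * PROTON_MASS) / ion.z


def enumerate_mixture_species(pa: Proteoform, pb: Proteoform) -> list[OligomerSpecies]:
    """All oligomer species of a two-proteoform trimerizing mixture.

    For distinct proteoforms: four trimers, three dimers, two monomers, in
    deterministic order (trimers, then dimers, then monomers; the unmodified
    form first).  Degenerate input (pa == pb) yields one of each.
    """
    order = [pa.id, pb.id]
    if pa.id == pb.id:
        return [
            OligomerSpecies.from_ids([pa.id] * n, order)
            for n in (3, 2, 1)
        ]
    out: list[OligomerSpecies] = []
    for size in (3, 2, 1):
        for n_b in range(0, size + 1):
            ids = [pa.id] * (size - n_b) + [pb.id] * n_b
            out.append(OligomerSpecies.from_ids(ids, order))
    return out


@dataclass(frozen=True)
class DissociationReaction:
    """A trimer educt ion and its dimer+monomer product alternatives.

    ``product_pairs`` lists every distinct way the trimer stoichiometry can
    split into a dimer and a released monomer (hetero-trimers have two release
    channels); ``product_charges`` maps role -> charge for one released pair
    and must sum to the educt charge.
    """

    educt: OligomerIon
    product_pairs: tuple[tuple[OligomerSpecies, OligomerSpecies], ...]
    product_charges: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.educt.species.role != "trimer":
            raise ValueError("dissociation reactions are defined for trimer educts only")
        for dimer, monomer in self.product_pairs:
            combined = Counter(dimer.stoichiometry) + Counter(monomer.stoichiometry)
            if combined != Counter(self.educt.species.stoichiometry):
                raise ValueError(
                    f"products {dimer.symbol} + {monomer.symbol} do not partition "
                    f"educt {self.educt.species.symbol}"
                )
        zsum = self.product_charges["dimer"] + self.product_charges["monomer"]
        if zsum != self.educt.z:
            raise ValueError(
                f"product charges {dict(self.product_charges)} do not sum to educt charge {self.educt.z}"
            )

    def product_ions(self) -> list[tuple[OligomerIon, OligomerIon]]:
        zd = self.product_charges["dimer"]
        zm = self.product_charges["monomer"]
        return [
            (OligomerIon(dimer, zd), OligomerIon(monomer, zm))
            for dimer, monomer in self.product_pairs
        ]


def dissociation_products(
    educt: OligomerIon,
    charge_split: tuple[int, int] | None = None,
    order: Sequence[str] | None = None,
) -> DissociationReaction:
    """Enumerate the dimer/monomer product pairs of a trimer educt ion.

    The default charge partition is dimer 3+/monomer 2+ for 5+ educts and
    4+/2+ for 6+ educts; other charges require an explicit ``charge_split``.
    """
    if educt.species.role != "trimer":
        raise ValueError(f"educt {educt.species.symbol!r} is not a trimer")
    if charge_split is None:
        try:
            charge_split = DEFAULT_CHARGE_SPLIT[educt.z]
        except KeyError:
            raise ValueError(
                f"no default charge split for educt charge {educt.z}+; pass charge_split"
            ) from None
    stoich = educt.species.stoichiometry
    pairs = []
    seen = set()
    for released in stoich:
        if released in seen:
            continue
        seen.add(released)
        rest = list(stoich)
        rest.remove(released)
        pairs.append(
            (OligomerSpecies.from_ids(rest, order), OligomerSpecies.from_ids([released], order))
        )
    return DissociationReaction(
        educt=educt,
        product_pairs=tuple(pairs),
        product_charges={"dimer": charge_split[0], "monomer": charge_split[1]},
    )
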