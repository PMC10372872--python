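"""Elemental-composition arithmetic for metal-loaded metallothionein species.

Metallothionein-3 (MT3) binds Cu(I) and Zn(II) through cysteine thiolates and
can carry intramolecular disulfides. In native electrospray the observed
neutral mass of a complex follows a charge-neutral hydrogen-displacement
model: each Cu(I) displaces one thiol proton, each Zn(II) two, and each
disulfide removes two hydrogens (2 RSH -> RSSR + 2H). This module provides
the composition bookkeeping behind that model together with average and
monoisotopic masses computed from a pinned isotope table.
"""

from __future__ import annotations

import functools
import importlib.resources
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as _pymass

__all__ = [
    "PROTON_MASS",
    "CANONICAL_RESIDUES",
    "ElementalComposition",
    "ProteinSequence",
    "MetalComplexSpecies",
    "isotope_table",
    "composition_from_sequence",
    "species_composition",
    "hydrogen_displacement",
    "average_mass",
    "monoisotopic_mass",
    "load_mt3",
]

#: Mass of the proton (Da); used for every m/z conversion (ionization adds
#: protons, not hydrogen atoms).
PROTON_MASS = 1.007276

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

_WATER = {"H": 2, "O": 1}


class ElementalComposition(Mapping):
    """Immutable element -> count map for a neutral molecule.

    Counts are non-negative integers; zero counts are dropped. Addition and
    subtraction are element-wise, and subtraction that would produce a
    negative count raises ``ValueError`` rather than clipping.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: dict[str, int] = {}
        for source in (counts or {}, kwargs):
            for element, n in source.items():
                if int(n) != n or n < 0:
                    raise ValueError(
                        f"count for element {element!r} must be a non-negative "
                        f"integer, got {n!r}"
                    )
                if n:
                    merged[element] = merged.get(element, 0) + int(n)
        self._counts = dict(sorted(merged.items()))

    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def get(self, element: str, default: int = 0) -> int:
        return self._counts.get(element, default)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalComposition):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __add__(self, other: Mapping[str, int]) -> "ElementalComposition":
        out = dict(self._counts)
        for element, n in other.items():
            out[element] = out.get(element, 0) + n
        return ElementalComposition(out)

    def __sub__(self, other: Mapping[str, int]) -> "ElementalComposition":
        out = dict(self._counts)
        for element, n in other.items():
            remaining = out.get(element, 0) - n
            if remaining < 0:
                raise ValueError(
                    f"subtraction would leave {remaining} atoms of {element}"
                )
            out[element] = remaining
        return ElementalComposition(out)

    def __mul__(self, factor: int) -> "ElementalComposition":
        if int(factor) != factor or factor < 0:
            raise ValueError("composition can only be scaled by a non-negative integer")
        return ElementalComposition({e: n * int(factor) for e, n in self._counts.items()})

    __rmul__ = __mul__

    def formula(self) -> str:
        """Hill-order molecular formula, e.g. ``C2H5NO2``."""
        items = dict(self._counts)
        parts = []
        for element in ("C", "H"):
            if element in items:
                n = items.pop(element)
                parts.append(element + (str(n) if n > 1 else ""))
        for element in sorted(items):
            n = items[element]
            parts.append(element + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __repr__(self) -> str:
        return f"ElementalComposition({self.formula()!r})"


@functools.lru_cache(maxsize=1)
def isotope_table() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pinned isotope table: element -> (masses Da, abundances), mass-sorted."""
    path = importlib.resources.files("metalloms.data") / "isotopes.csv"
    with importlib.resources.as_file(path) as p:
        table = pd.read_csv(p, comment="#")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for element, group in table.groupby("element", sort=False):
        group = group.sort_values("mass")
        out[str(element)] = (
            group["mass"].to_numpy(float),
            group["abundance"].to_numpy(float),
        )
    return out


def _require_element(element: str) -> tuple[np.ndarray, np.ndarray]:
    table = isotope_table()
    if element not in table:
        raise KeyError(f"element {element!r} is not in the bundled isotope table")
    return table[element]


def average_mass(composition: Mapping[str, int]) -> float:
    """Abundance-weighted mean mass of a neutral composition, in Da."""
    total = 0.0
    for element, n in composition.items():
        masses, abundances = _require_element(element)
        total += n * float(np.dot(masses, abundances) / abundances.sum())
    return total


def monoisotopic_mass(composition: Mapping[str, int]) -> float:
    """Sum of the most-abundant-isotope masses per element, in Da."""
    total = 0.0
    for element, n in composition.items():
        masses, abundances = _require_element(element)
        total += n * float(masses[np.argmax(abundances)])
    return total


@dataclass(frozen=True)
class ProteinSequence:
    """Validated one-letter amino-acid sequence (20 canonical residues only)."""

    residues: str
    name: str = ""

    def __post_init__(self) -> None:
        seq = self.residues.upper()
        if not seq:
            raise ValueError("sequence must contain at least one residue")
        for position, code in enumerate(seq, start=1):
            if code not in CANONICAL_RESIDUES:
                raise ValueError(
                    f"non-canonical residue {code!r} at position {position}"
                )
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_cys(self) -> int:
        return self.residues.count("C")

    def prefix(self, length: int) -> "ProteinSequence":
        return ProteinSequence(self.residues[:length], name=f"{self.name}[1:{length}]")

    def suffix(self, length: int) -> "ProteinSequence":
        start = len(self.residues) - length
        return ProteinSequence(self.residues[start:], name=f"{self.name}[{start + 1}:]")


def composition_from_sequence(seq: ProteinSequence | str) -> ElementalComposition:
    """Neutral, fully reduced composition of a free-termini polypeptide.

    Sum of residue compositions plus one water (free amine / free acid
    termini); all cysteine thiols protonated.
    """
    if isinstance(seq, str):
        seq = ProteinSequence(seq)
    counts: dict[str, int] = dict(_WATER)
    for code in seq.residues:
        for element, n in _pymass.std_aa_comp[code].items():
            counts[element] = counts.get(element, 0) + n
    return ElementalComposition(counts)


def hydrogen_displacement(n_cu: int, n_zn: int, n_ss: int) -> int:
    """Hydrogens displaced by metalation/oxidation: n_cu + 2*n_zn + 2*n_ss."""
    return n_cu + 2 * n_zn + 2 * n_ss


@dataclass(frozen=True)
class MetalComplexSpecies:
    """A protein carrying Cu(I)/Zn(II) ions and intramolecular disulfides.

    The default thiol budget requires ``n_cu + n_zn + 2*n_ss <= n_cys``: each
    metal claims at least one dedicated thiolate and each disulfide consumes
    two cysteines. Real thiolate clusters bridge metals, so the budget can be
    relaxed (``enforce_thiol_budget=False``) when modelling denser
    coordination. Hydrogen displacement may never exceed the number of labile
    (thiol) hydrogens.
    """

    base: ProteinSequence
    n_cu: int = 0
    n_zn: int = 0
    n_ss: int = 0
    label: str = ""
    enforce_thiol_budget: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        for name in ("n_cu", "n_zn", "n_ss"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        n_cys = self.base.n_cys
        if self.n_h > n_cys:
            raise ValueError(
                f"hydrogen displacement {self.n_h} exceeds the {n_cys} labile "
                f"thiol hydrogens of {self.base.name or 'the sequence'}"
            )
        if self.enforce_thiol_budget and self.n_cu + self.n_zn + 2 * self.n_ss > n_cys:
            raise ValueError(
                f"thiol budget violated: n_cu + n_zn + 2*n_ss = "
                f"{self.n_cu + self.n_zn + 2 * self.n_ss} > {n_cys} cysteines"
            )

    @property
    def n_h(self) -> int:
        """Hydrogens displaced relative to the apo, fully reduced protein."""
        return hydrogen_displacement(self.n_cu, self.n_zn, self.n_ss)

    @property
    def stoichiometry(self) -> tuple[int, int, int]:
        return (self.n_cu, self.n_zn, self.n_ss)

    def describe(self) -> str:
        if self.label:
            return self.label
        name = self.base.name or "protein"
        return f"Cu{self.n_cu}Zn{self.n_zn}{name}(ss{self.n_ss})"


def species_composition(sp: MetalComplexSpecies) -> ElementalComposition:
    """Neutral composition of a metal complex under hydrogen displacement.

    apo + n_cu*Cu + n_zn*Zn - n_h*H with n_h = n_cu + 2*n_zn + 2*n_ss, i.e.
    metal uptake and disulfide formation are charge-neutral at the protein.
    """
    comp = composition_from_sequence(sp.base)
    extra: dict[str, int] = {}
    if sp.n_cu:
        extra["Cu"] = sp.n_cu
    if sp.n_zn:
        extra["Zn"] = sp.n_zn
    comp = comp + extra
    return comp - {"H": sp.n_h}


def load_mt3() -> ProteinSequence:
    """Bundled human metallothionein-3 sequence (UniProt P25713, 68 residues)."""
    path = importlib.resources.files("metalloms.data") / "mt3_p25713.fasta"
    lines = path.read_text().splitlines()
    name = lines[0].lstrip(">").split()[0]
    return ProteinSequence("".join(lines[1:]), name=name)
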