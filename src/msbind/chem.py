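"""Molecular-formula arithmetic and the packaged lipid mass table.

Lipid-bound species in a native mass spectrum appear as mass adducts on the
protein's charge states; assigning them requires exact neutral masses for the
candidate lipids.  This module provides integer elemental formulas, average and
monoisotopic masses computed from a baked-in atomic-weight table (IUPAC
standard atomic weights, four decimal places, so results do not depend on any
external resource), and the glycerophospholipid / phosphoinositide panel used
throughout the package.

Lipids are modeled as free acids, not salts: the ~863 Da adduct spacing seen on
a delipidated transporter matches the free-acid average mass of di-18:1
phosphatidylinositol (C45H83O13P).  Phosphoinositides form an exact HPO3
ladder: PI -> PI(4)P -> PI(4,5)P2 -> PIP3 each add one HPO3 (~80 Da).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterator, Mapping

__all__ = [
    "AVERAGE_WEIGHTS",
    "MONOISOTOPIC_WEIGHTS",
    "PROTON_MASS",
    "HPO3",
    "MolecularFormula",
    "LipidSpecies",
    "formula_mass",
    "lipid_table",
    "get_lipid",
    "modification_mass",
    "MODIFICATIONS",
    "write_lipid_csv",
    "read_lipid_csv",
]

#: IUPAC standard atomic weights, rounded to four decimal places.
AVERAGE_WEIGHTS: Mapping[str, float] = MappingProxyType(
    {
        "H": 1.0080,
        "C": 12.0110,
        "N": 14.0070,
        "O": 15.9990,
        "P": 30.9738,
        "S": 32.0600,
        "Na": 22.9898,
    }
)

#: Masses of the principal isotope, four decimal places.
MONOISOTOPIC_WEIGHTS: Mapping[str, float] = MappingProxyType(
    {
        "H": 1.0078,
        "C": 12.0000,
        "N": 14.0031,
        "O": 15.9949,
        "P": 30.9738,
        "S": 31.9721,
        "Na": 22.9898,
    }
)

#: Mass of a proton in Da, used for positive-mode m/z arithmetic.
PROTON_MASS = 1.00728

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_ACYL_PAIR = re.compile(r"^(?:d?)(\d+):(\d+)$")


class UnknownElementError(KeyError):
    """Raised when a formula contains an element missing from the weight table."""


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition with non-negative integer counts.

    Supports addition (formula arithmetic is mass-additive) and scalar
    multiplication; the empty formula has mass zero.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for element, count in self.counts.items():
            if not isinstance(count, int):
                raise TypeError(f"count for {element!r} must be an integer, got {count!r}")
            if count < 0:
                raise ValueError(f"negative count for element {element!r}")
            if count > 0:
                clean[element] = count
        object.__setattr__(self, "counts", MappingProxyType(dict(clean)))

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        """Parse a Hill-notation formula string such as ``"C45H83O13P"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            if not match.group(0):
                break
            element = match.group(1)
            counts[element] = counts.get(element, 0) + int(match.group(2) or 1)
            pos = match.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) + count
        return MolecularFormula(merged)

    def __mul__(self, n: int) -> "MolecularFormula":
        return MolecularFormula({el: c * n for el, c in self.counts.items()})

    __rmul__ = __mul__

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts.items())

    def mass(self, kind: str = "average") -> float:
        return formula_mass(self, kind)

    def __str__(self) -> str:
        # Hill notation: C, then H, then other elements alphabetically.
        parts = []
        for element in ("C", "H"):
            if element in self.counts:
                n = self.counts[element]
                parts.append(f"{element}{n if n > 1 else ''}")
        for element in sorted(self.counts):
            if element in ("C", "H"):
                continue
            n = self.counts[element]
            parts.append(f"{element}{n if n > 1 else ''}")
        return "".join(parts)


def formula_mass(formula: MolecularFormula | str, kind: str = "average") -> float:
    """Sum of count x atomic weight over the formula, in Da.

    ``kind`` selects the atomic-weight table: ``"average"`` or
    ``"monoisotopic"``.  Rounding is the caller's concern.
    """
    if isinstance(formula, str):
        formula = MolecularFormula.from_string(formula)
    if kind == "average":
        table = AVERAGE_WEIGHTS
    elif kind == "monoisotopic":
        table = MONOISOTOPIC_WEIGHTS
    else:
        raise ValueError(f"kind must be 'average' or 'monoisotopic', got {kind!r}")
    total = 0.0
    for element, count in formula:
        try:
            weight = table[element]
        except KeyError:
            raise UnknownElementError(
                f"element {element!r} is not in the atomic-weight table"
            ) from None
        total += count * weight
    return total


#: One phosphate increment of the phosphoinositide ladder.
HPO3 = MolecularFormula.from_string("HPO3")


def _parse_acyl(acyl: str) -> tuple[tuple[int, int], ...]:
    """Parse acyl-chain shorthand like ``"18:1/18:1"`` or ``"16:0-18:1"``."""
    chains = re.split(r"[/-]", acyl)
    parsed = []
    for chain in chains:
        m = _ACYL_PAIR.match(chain.strip())
        if m is None:
            raise ValueError(f"cannot parse acyl composition {acyl!r}")
        parsed.append((int(m.group(1)), int(m.group(2))))
    return tuple(parsed)


@dataclass(frozen=True)
class LipidSpecies:
    """A named lipid with class tag, acyl composition, and elemental formula."""

    name: str
    lipid_class: str
    acyl: str
    formula: MolecularFormula

    def __post_init__(self) -> None:
        _parse_acyl(self.acyl)  # reject unknown acyl nomenclature outright
        if self.average_mass <= 0:
            raise ValueError(f"lipid {self.name!r} has non-positive mass")

    @property
    def average_mass(self) -> float:
        return self.formula.mass("average")

    @property
    def monoisotopic_mass(self) -> float:
        return self.formula.mass("monoisotopic")


# Free-acid formulas. The phosphoinositides (di-18:1) are built from the PI
# formula by exact HPO3 increments; the glycerophospholipid panel carries
# 1-palmitoyl-2-oleoyl (16:0-18:1) chains; S1P is the d18:1 lysolipid substrate.
_PI = MolecularFormula.from_string("C45H83O13P")

_LIPID_DEFS: tuple[LipidSpecies, ...] = (
    LipidSpecies("PI(18:1/18:1)", "PI", "18:1/18:1", _PI),
    LipidSpecies("PI(4)P(18:1/18:1)", "PI4P", "18:1/18:1", _PI + HPO3),
    LipidSpecies("PI(4,5)P2(18:1/18:1)", "PIP2", "18:1/18:1", _PI + 2 * HPO3),
    LipidSpecies("PI(3,4,5)P3(18:1/18:1)", "PIP3", "18:1/18:1", _PI + 3 * HPO3),
    LipidSpecies("PA(16:0/18:1)", "PA", "16:0/18:1", MolecularFormula.from_string("C37H71O8P")),
    LipidSpecies("PS(16:0/18:1)", "PS", "16:0/18:1", MolecularFormula.from_string("C40H76NO10P")),
    LipidSpecies("PG(16:0/18:1)", "PG", "16:0/18:1", MolecularFormula.from_string("C40H77O10P")),
    LipidSpecies("PE(16:0/18:1)", "PE", "16:0/18:1", MolecularFormula.from_string("C39H76NO8P")),
    LipidSpecies("PC(16:0/18:1)", "PC", "16:0/18:1", MolecularFormula.from_string("C42H82NO8P")),
    LipidSpecies("S1P(d18:1)", "S1P", "18:1", MolecularFormula.from_string("C18H38NO5P")),
)

#: Registered modification mass deltas in Da (immutable after load).
MODIFICATIONS: Mapping[str, float] = MappingProxyType(
    {
        # C2H2O on the alpha-amine, the most common eukaryotic N-terminal mark.
        "N-terminal acetylation": formula_mass("C2H2O", "average"),
    }
)


def modification_mass(name: str) -> float:
    try:
        return MODIFICATIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown modification {name!r}; registered: {sorted(MODIFICATIONS)}"
        ) from None


def lipid_table() -> list[LipidSpecies]:
    """The built-in lipid panel (fresh list; entries are immutable)."""
    return list(_LIPID_DEFS)


def get_lipid(name: str) -> LipidSpecies:
    """Look up a panel lipid by exact name or by class tag (e.g. ``"PIP2"``)."""
    for lipid in _LIPID_DEFS:
        if lipid.name == name or lipid.lipid_class == name:
            return lipid
    raise KeyError(f"unknown lipid {name!r}; known: {[l.name for l in _LIPID_DEFS]}")


def write_lipid_csv(path, lipids: list[LipidSpecies] | None = None) -> None:
    """Export the lipid table as ``name,class,acyl,formula`` (Hill notation)."""
    lipids = lipid_table() if lipids is None else lipids
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["name", "class", "acyl", "formula"])
        for lipid in lipids:
            writer.writerow([lipid.name, lipid.lipid_class, lipid.acyl, str(lipid.formula)])


def read_lipid_csv(path) -> list[LipidSpecies]:
    """Read a lipid table written by :func:`write_lipid_csv` (extension point)."""
    out = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle):
            out.append(
                LipidSpecies(
                    name=row["name"],
                    lipid_class=row["class"],
                    acyl=row["acyl"],
                    formula=MolecularFormula.from_string(row["formula"]),
                )
            )
    return out
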