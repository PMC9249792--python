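"""Elemental formulas and negative-mode ion chemistry.

Single-cell sap analysed by pressure-probe ESI in negative ion mode yields
deprotonated [M - H]-, chloride-adducted [M + Cl]-, doubly deprotonated
[M - 2H]2- and cluster [M' - H]- species.  This module turns an elemental
composition into the theoretical m/z of each of those ion types.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "ElementalFormula",
    "IonMode",
    "IonSpecies",
    "AcylComposition",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "CHLORIDE_MASS",
    "cardiolipin_formula",
    "ion_mz",
    "monoisotopic_mass",
]

# Monoisotopic masses of the most abundant isotope, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Cl": 34.96885271,
    "Na": 22.98976928,
}

#: Mass removed per deprotonation (the electron mass is neglected; the
#: resulting bias is < 0.5 ppm at these masses, below reporting precision).
PROTON_MASS = 1.007276
#: Mass added by a 35Cl- adduct.
CHLORIDE_MASS = 34.968853

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count map over {C, H, N, O, P, S, Cl, Na}.

    Counts are nonnegative integers with at least one positive count, so the
    monoisotopic mass is strictly positive.  Formulas add element-wise, which
    is how noncovalent cluster compositions are built.
    """

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for element, n in self.counts:
            if element not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {element!r}")
            if n < 0 or n != int(n):
                raise ValueError(f"negative or non-integer count for {element}: {n}")
        if not any(n > 0 for _, n in self.counts):
            raise ValueError("formula must contain at least one atom")

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``C6H12O6``."""
        text = text.strip()
        if not text:
            raise ValueError("empty formula string")
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise ValueError(f"malformed formula {text!r} at position {pos}")
            if not match.group(0):
                break
            element = match.group(1)
            n = int(match.group(2)) if match.group(2) else 1
            counts[element] = counts.get(element, 0) + n
            pos = match.end()
        if pos != len(text):
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        return cls.from_dict(counts)

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "ElementalFormula":
        items = tuple(sorted((el, int(n)) for el, n in counts.items() if n))
        return cls(items)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = self.as_dict()
        for element, n in other.counts:
            merged[element] = merged.get(element, 0) + n
        return ElementalFormula.from_dict(merged)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da."""
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.counts)

    def __str__(self) -> str:
        order = ["C", "H"] + sorted(set(dict(self.counts)) - {"C", "H"})
        counts = self.as_dict()
        return "".join(
            f"{el}{counts[el] if counts[el] != 1 else ''}"
            for el in order
            if el in counts
        )


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic mass (Da) of a formula or formula string."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    return formula.mass


class IonMode(str, Enum):
    """Negative-mode ionization rules observed in pressure-probe ESI spectra."""

    DEPROTONATED = "deprotonated"            # [M - H]-
    CHLORIDE = "chloride"                    # [M + Cl]-
    DOUBLE_DEPROTONATED = "double_deprotonated"  # [M - 2H]2-
    CLUSTER_DEPROTONATED = "cluster_deprotonated"  # [M' - H]-, M' a cluster


@dataclass(frozen=True)
class IonSpecies:
    """One or more constituent formulas plus an ionization rule.

    Charge 2 is only meaningful for the doubly deprotonated mode; the cluster
    mode requires at least two constituents (a noncovalent aggregate).
    """

    constituents: tuple[ElementalFormula, ...]
    mode: IonMode
    charge: int = field(default=1)

    def __post_init__(self) -> None:
        if not self.constituents:
            raise ValueError("ion needs at least one constituent formula")
        if self.charge not in (1, 2):
            raise ValueError(f"charge must be 1 or 2, got {self.charge}")
        if self.charge == 2 and self.mode is not IonMode.DOUBLE_DEPROTONATED:
            raise ValueError("charge 2 requires the double-deprotonated mode")
        if self.mode is IonMode.DOUBLE_DEPROTONATED and self.charge != 2:
            raise ValueError("double-deprotonated mode carries charge 2")
        if self.mode is IonMode.CLUSTER_DEPROTONATED and len(self.constituents) < 2:
            raise ValueError("cluster mode requires >= 2 constituents")
        if self.mode is not IonMode.CLUSTER_DEPROTONATED and len(self.constituents) > 1:
            raise ValueError("multiple constituents require the cluster mode")

    @classmethod
    def make(
        cls,
        formula: ElementalFormula | str | list | tuple,
        mode: IonMode | str,
    ) -> "IonSpecies":
        mode = IonMode(mode)
        if isinstance(formula, (list, tuple)):
            constituents = tuple(
                f if isinstance(f, ElementalFormula) else ElementalFormula.parse(f)
                for f in formula
            )
        elif isinstance(formula, ElementalFormula):
            constituents = (formula,)
        else:
            constituents = (ElementalFormula.parse(formula),)
        charge = 2 if mode is IonMode.DOUBLE_DEPROTONATED else 1
        return cls(constituents, mode, charge)

    @property
    def neutral_mass(self) -> float:
        return sum(f.mass for f in self.constituents)

    @property
    def mz(self) -> float:
        return ion_mz(self)


def ion_mz(ion: IonSpecies) -> float:
    """Theoretical m/z (Th) of a negative-mode ion species."""
    m = ion.neutral_mass
    if ion.mode is IonMode.DEPROTONATED:
        return m - PROTON_MASS
    if ion.mode is IonMode.CHLORIDE:
        return m + CHLORIDE_MASS
    if ion.mode is IonMode.DOUBLE_DEPROTONATED:
        return (m - 2.0 * PROTON_MASS) / 2.0
    if ion.mode is IonMode.CLUSTER_DEPROTONATED:
        return m - PROTON_MASS
    raise ValueError(f"unsupported ion mode: {ion.mode}")  # pragma: no cover


@dataclass(frozen=True, order=True)
class AcylComposition:
    """Total acyl carbon : double-bond shorthand, e.g. CL(70:4) or PG(34:1)."""

    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.carbons <= 0 or self.carbons % 2 != 0:
            raise ValueError(f"acyl carbons must be a positive even integer: {self.carbons}")
        if self.double_bonds < 0 or self.double_bonds > self.carbons // 2:
            raise ValueError(
                f"double bonds must lie in [0, carbons/2]: {self.double_bonds}"
            )

    @classmethod
    def parse(cls, text: str) -> "AcylComposition":
        c, d = text.split(":")
        return cls(int(c), int(d))

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"


def cardiolipin_formula(acyl: AcylComposition) -> ElementalFormula:
    """Elemental formula of a cardiolipin with total acyl composition n:d.

    Cardiolipin is a diphosphatidylglycerol: two phosphatidic acids joined by
    a central glycerol, giving C(n+9) H(2n-2d+14) O17 P2 for n acyl carbons
    and d double bonds.  Detected as [M - 2H]2- in negative mode.
    """
    n, d = acyl.carbons, acyl.double_bonds
    return ElementalFormula.from_dict(
        {"C": n + 9, "H": 2 * n - 2 * d + 14, "O": 17, "P": 2}
    )
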