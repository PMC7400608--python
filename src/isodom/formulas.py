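"""Exact-mass arithmetic for CHNOPS molecular formulas with an explicit 12C/13C split.

A molecular formula here is an *isotopologue*: the number of 12C and 13C
atoms is tracked separately, so the same elemental composition at different
13C enrichment levels are distinct formulas with distinct exact masses.
This is the representation needed for stable-isotope-probing experiments in
which a fully 13C-labeled substrate is followed against an unlabeled
dissolved-organic-matter background.

Masses are CODATA/AME monoisotopic values.  Only the most abundant isotope
of H, N, O, P and S is modeled; carbon is the only element with two
isotopes, which is what ultrahigh-resolution 13C-tracer assignment requires.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "ElementMassTable",
    "DEFAULT_MASSES",
    "MolecularFormula",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "mass_error_ppm",
    "dbe",
    "labeling_percent",
    "heteroatom_class",
]


@dataclass(frozen=True)
class ElementMassTable:
    """Monoisotopic masses (Da) of the modeled isotopes plus the electron mass.

    ``natural_13c_fraction`` is the natural 13C atom fraction used as the
    baseline for atom-percent-excess arithmetic (1.07 atom%).
    """

    h: float = 1.00782503207
    c12: float = 12.0
    c13: float = 13.00335483507
    n: float = 14.0030740048
    o: float = 15.99491461956
    p: float = 30.97376163
    s: float = 31.97207100
    electron: float = 0.00054857990907
    natural_13c_fraction: float = 0.0107

    def __post_init__(self) -> None:
        for name in ("h", "c12", "c13", "n", "o", "p", "s", "electron"):
            if getattr(self, name) <= 0:
                raise ValueError(f"isotope mass {name!r} must be positive")
        delta = self.c13 - self.c12
        if not (1.00335 - 1e-5 < delta < 1.00335 + 1e-5):
            raise ValueError(f"13C-12C mass difference {delta} outside expected range")
        if not (0.010 < self.natural_13c_fraction < 0.012):
            raise ValueError("natural 13C fraction outside the plausible range")

    @property
    def proton(self) -> float:
        """Mass of a proton (1H minus one electron), Da."""
        return self.h - self.electron

    @property
    def c13_delta(self) -> float:
        """Mass difference between 13C and 12C, Da."""
        return self.c13 - self.c12


DEFAULT_MASSES = ElementMassTable()


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """An isotopologue-resolved CHNOPS formula.

    ``c12`` and ``c13`` count carbon atoms by isotope; ``h``..``s`` count the
    remaining elements.  At least one carbon atom is required — carbon-free
    compositions are not molecular formulas in this context.
    """

    c12: int = 0
    c13: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    p: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for name in ("c12", "c13", "h", "n", "o", "p", "s"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise TypeError(f"atom count {name!r} must be an integer")
            if value < 0:
                raise ValueError(f"atom count {name!r} must be non-negative")
        if self.c12 + self.c13 < 1:
            raise ValueError("a molecular formula needs at least one carbon atom")

    @property
    def c_total(self) -> int:
        return self.c12 + self.c13

    @property
    def labeling_fraction(self) -> float:
        return self.c13 / self.c_total

    def __str__(self) -> str:
        parts = []
        if self.c13:
            parts.append(f"[13C]{self.c13}")
        if self.c12:
            parts.append(f"C{self.c12}")
        for symbol, count in (("H", self.h), ("N", self.n), ("O", self.o),
                              ("P", self.p), ("S", self.s)):
            if count:
                parts.append(f"{symbol}{count}")
        return " ".join(parts)


_TOKEN = re.compile(r"(\[13C\]|C|H|N|O|P|S)(\d+)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse the text form produced by ``str(MolecularFormula)``.

    Tokens are ``[13C]k`` plus element symbols with explicit counts, e.g.
    ``"[13C]6 C3 H14 O5"``.
    """
    counts = {"c12": 0, "c13": 0, "h": 0, "n": 0, "o": 0, "p": 0, "s": 0}
    key = {"[13C]": "c13", "C": "c12", "H": "h", "N": "n", "O": "o", "P": "p", "S": "s"}
    consumed = 0
    for match in _TOKEN.finditer(text):
        counts[key[match.group(1)]] += int(match.group(2))
        consumed += len(match.group(0))
    if consumed != len(text.replace(" ", "")):
        raise ValueError(f"cannot parse formula string {text!r}")
    return MolecularFormula(**counts)


def monoisotopic_mass(formula: MolecularFormula,
                      masses: ElementMassTable = DEFAULT_MASSES) -> float:
    """Neutral monoisotopic mass (Da): the sum of per-isotope atomic masses."""
    return (formula.c12 * masses.c12 + formula.c13 * masses.c13
            + formula.h * masses.h + formula.n * masses.n
            + formula.o * masses.o + formula.p * masses.p
            + formula.s * masses.s)


def ion_mz(formula: MolecularFormula,
           masses: ElementMassTable = DEFAULT_MASSES) -> float:
    """m/z of the singly deprotonated ion [M-H]-.

    Negative-mode electrospray of dissolved organic matter overwhelmingly
    produces the even-electron [M-H]- ion, so this is the only ion type
    modeled.  A formula without hydrogen cannot deprotonate.
    """
    if formula.h < 1:
        raise ValueError("cannot deprotonate a hydrogen-free formula")
    return monoisotopic_mass(formula, masses) - masses.proton


def mass_error_ppm(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be positive")
    return 1e6 * (observed_mz - theoretical_mz) / theoretical_mz


def dbe(formula: MolecularFormula) -> float:
    """Double-bond equivalents of the neutral molecule.

    DBE = C - H/2 + N/2 + 1.  P and S are treated as non-contributing, the
    usual convention for marine DOM formula filtering.
    """
    return formula.c_total - formula.h / 2 + formula.n / 2 + 1


def labeling_percent(formula: MolecularFormula) -> float:
    """Percentage of the formula's carbon atoms that are 13C."""
    return 100.0 * formula.c13 / formula.c_total


def heteroatom_class(formula: MolecularFormula) -> str:
    """Heteroatom class label: CHO, N, P or NP (by N/P content only)."""
    if formula.n > 0 and formula.p > 0:
        return "NP"
    if formula.n > 0:
        return "N"
    if formula.p > 0:
        return "P"
    return "CHO"
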