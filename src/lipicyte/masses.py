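"""Monoisotopic mass arithmetic for precursor and fragment ions.

Exact-mass annotation needs only a handful of elements (lipid formulas over
C/H/N/O/P/S plus the Na/K charge carriers), so the mass table is kept
in-package rather than pulling in a general chemistry dependency.
Values are CODATA/NIST principal-isotope masses in Da.
"""

from __future__ import annotations

import re

__all__ = [
    "MONOISOTOPIC",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "parse_formula",
    "formula_mass",
    "ADDUCTS",
    "adduct_mz",
    "neutral_mass",
    "ppm_error",
]

MONOISOTOPIC: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

ELECTRON_MASS = 0.000548579909
#: mass of H+ (hydrogen atom minus one electron)
PROTON_MASS = MONOISOTOPIC["H"] - ELECTRON_MASS

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style elemental formula such as ``C42H82NO8P``.

    Returns element → count. The empty string parses to an empty
    composition (mass 0). Unknown element symbols raise ``ValueError``.
    """
    composition: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"malformed formula {formula!r} at position {pos}")
        pos = match.end()
        element, count = match.group(1), match.group(2)
        if element not in MONOISOTOPIC:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        composition[element] = composition.get(element, 0) + (int(count) if count else 1)
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r} at position {pos}")
    return composition


def formula_mass(formula: str | dict[str, int]) -> float:
    """Monoisotopic (principal-isotope) mass of a neutral formula, in Da."""
    composition = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(MONOISOTOPIC[el] * n for el, n in composition.items())


class Adduct:
    """One row of the adduct table: m/z = (n·M + offset) / |charge|."""

    __slots__ = ("label", "n", "offset", "charge", "mode")

    def __init__(self, label: str, n: int, offset: float, charge: int, mode: str):
        self.label = label
        self.n = n
        self.offset = offset
        self.charge = charge
        self.mode = mode  # "+" or "-"

    def mz(self, neutral: float) -> float:
        return (self.n * neutral + self.offset) / abs(self.charge)

    def neutral(self, mz: float) -> float:
        return (mz * abs(self.charge) - self.offset) / self.n

    def __repr__(self) -> str:  # pragma: no cover
        return f"Adduct({self.label})"


_NH4 = formula_mass("NH4") - ELECTRON_MASS       # ammonium cation
_NA = MONOISOTOPIC["Na"] - ELECTRON_MASS         # sodium cation
_HCOO = formula_mass("CHO2") + ELECTRON_MASS     # formate anion

#: Default adducts for a formate/ammonium-formate mobile phase:
#: positive mode [M+H]+, [M+NH4]+, [M+Na]+; negative mode [M-H]-, [M+HCOO]-.
ADDUCTS: dict[str, Adduct] = {
    a.label: a
    for a in (
        Adduct("[M+H]+", 1, PROTON_MASS, +1, "+"),
        Adduct("[M+NH4]+", 1, _NH4, +1, "+"),
        Adduct("[M+Na]+", 1, _NA, +1, "+"),
        Adduct("[M-H]-", 1, -PROTON_MASS, -1, "-"),
        Adduct("[M+HCOO]-", 1, _HCOO, -1, "-"),
    )
}


def adduct_mz(mass: float, adduct: str, table: dict[str, Adduct] | None = None) -> float:
    """m/z of a neutral monoisotopic ``mass`` under ``adduct`` (e.g. ``[M+H]+``)."""
    table = ADDUCTS if table is None else table
    if adduct not in table:
        raise KeyError(f"unknown adduct {adduct!r}")
    return table[adduct].mz(mass)


def neutral_mass(mz: float, adduct: str, table: dict[str, Adduct] | None = None) -> float:
    """Invert :func:`adduct_mz`."""
    table = ADDUCTS if table is None else table
    if adduct not in table:
        raise KeyError(f"unknown adduct {adduct!r}")
    return table[adduct].neutral(mz)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error in parts per million: 1e6·(obs − theo)/theo."""
    return 1e6 * (observed - theoretical) / theoretical


def fragment_mz(formula: str | dict[str, int], mode: str) -> float:
    """m/z of a fragment ion given the ion's elemental formula.

    The formula describes the ion's atoms; the electron is added or removed
    according to ``mode`` ("+" → cation, "-" → anion). E.g. the
    phosphocholine head-group cation C5H15NO4P+ gives 184.0733.
    """
    m = formula_mass(formula)
    if mode == "+":
        return m - ELECTRON_MASS
    if mode == "-":
        return m + ELECTRON_MASS
    raise ValueError(f"ion mode must be '+' or '-', got {mode!r}")
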