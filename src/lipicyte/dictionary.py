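"""Lipid dictionary: shorthand nomenclature, subclass taxonomy, and the
built-in annotation dictionary.

Shorthand grammar
-----------------
Names follow the common sum-composition / fatty-acyl convention::

    PC(38:2)                     sum composition: 38 carbons, 2 double bonds
    PC(38:2) > PC(18:1_20:1)     '>' refines to fatty-acyl level; '_' means
                                 sn-position unknown, '/' means known
    PE(O-16:1/20:3)              'O-' ether linkage, 'P-' plasmalogen
    Cer(d36:2)                   'd' marks the dihydroxy sphingoid backbone
    FA(16:0), Car(18:1)          free fatty acids and acylcarnitines

Neutral elemental formulas are derived from per-subclass composition rules
(backbone plus total acyl carbons/double bonds); ether linkage replaces one
ester oxygen (O−1, H+2) and a plasmalogen is an ether with one additional
double bond hidden in the vinyl-ether.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

from .masses import ADDUCTS, Adduct, adduct_mz, formula_mass, parse_formula

__all__ = [
    "SUBCLASS_TO_CLASS",
    "SUBCLASSES",
    "Shorthand",
    "parse_shorthand",
    "print_shorthand",
    "formula_for",
    "LipidEntry",
    "LipidDictionary",
    "default_dictionary",
]

#: Subclass → lipid class, following the four-class grouping used for
#: brain lipidomics panels (fatty acids, glycerolipids, phospholipids,
#: sphingolipids). "SPB" denotes sphingoid bases.
SUBCLASS_TO_CLASS: dict[str, str] = {
    "Car": "fatty acid",
    "FFA": "fatty acid",
    "DG": "glycerolipid",
    "PA": "glycerolipid",
    "PG": "glycerolipid",
    "TG": "glycerolipid",
    "CL": "phospholipid",
    "LPC": "phospholipid",
    "LPE": "phospholipid",
    "PC": "phospholipid",
    "PE": "phospholipid",
    "PI": "phospholipid",
    "PS": "phospholipid",
    "Cer": "sphingolipid",
    "HexCer": "sphingolipid",
    "SGL": "sphingolipid",
    "SM": "sphingolipid",
    "SPB": "sphingolipid",
}

SUBCLASSES = tuple(SUBCLASS_TO_CLASS)

# Name prefix used in shorthand for each subclass (FFA species are written
# "FA(16:0)"; sphingoid bases "SPB(18:1)").
_PREFIX_TO_SUBCLASS = {**{s: s for s in SUBCLASSES}, "FA": "FFA"}
_SUBCLASS_TO_PREFIX = {s: s for s in SUBCLASSES}
_SUBCLASS_TO_PREFIX["FFA"] = "FA"


@dataclass(frozen=True)
class Shorthand:
    """Structured decomposition of a lipid shorthand name."""

    subclass: str
    total_c: int
    total_db: int
    chains: tuple[tuple[int, int], ...] = ()
    positions_known: bool = False
    ether: str | None = None        # None | "O" | "P"
    hydroxyl: str | None = None     # sphingoid prefix, e.g. "d"
    refinement: "Shorthand | None" = None

    @property
    def naming_level(self) -> str:
        if self.chains or (self.refinement is not None and self.refinement.chains):
            return "fatty-acyl"
        return "species"


_HEAD = re.compile(
    r"^(?P<prefix>[A-Za-z]+)\("
    r"(?P<ether>[OP]-)?(?P<hydroxyl>[dt])?"
    r"(?P<body>\d+:\d+(?:[_/]\d+:\d+)*)\)$"
)


def _parse_single(name: str) -> Shorthand:
    m = _HEAD.match(name.strip())
    if m is None:
        raise ValueError(f"malformed lipid shorthand: {name!r}")
    prefix = m.group("prefix")
    if prefix not in _PREFIX_TO_SUBCLASS:
        raise ValueError(f"unknown lipid subclass prefix {prefix!r} in {name!r}")
    subclass = _PREFIX_TO_SUBCLASS[prefix]
    ether = m.group("ether")[0] if m.group("ether") else None
    hydroxyl = m.group("hydroxyl")
    body = m.group("body")
    sep = "/" if "/" in body else "_"
    parts = [tuple(int(v) for v in chunk.split(":")) for chunk in body.split(sep)]
    if len(parts) == 1:
        c, db = parts[0]
        return Shorthand(subclass, c, db, (), False, ether, hydroxyl)
    chains = tuple((c, d) for c, d in parts)
    total_c = sum(c for c, _ in chains)
    total_db = sum(d for _, d in chains)
    return Shorthand(subclass, total_c, total_db, chains, sep == "/", ether, hydroxyl)


def parse_shorthand(name: str) -> Shorthand:
    """Parse a shorthand name, optionally with a ``>`` fatty-acyl refinement.

    For refined names (``PC(38:2) > PC(18:1_20:1)``) the chain carbons and
    double bonds must sum to the sum-composition values.
    """
    if ">" in name:
        summary_str, refinement_str = name.split(">", 1)
        summary = _parse_single(summary_str)
        refinement = _parse_single(refinement_str)
        if refinement.subclass != summary.subclass:
            raise ValueError(f"refinement subclass differs in {name!r}")
        if (refinement.total_c, refinement.total_db) != (summary.total_c, summary.total_db):
            raise ValueError(
                f"refinement chains do not sum to the sum composition in {name!r}"
            )
        return Shorthand(
            summary.subclass, summary.total_c, summary.total_db,
            refinement.chains, refinement.positions_known,
            summary.ether or refinement.ether, summary.hydroxyl or refinement.hydroxyl,
            refinement,
        )
    return _parse_single(name)


def _print_single(
    subclass: str, c: int, db: int, chains=(), positions_known=False,
    ether=None, hydroxyl=None,
) -> str:
    prefix = _SUBCLASS_TO_PREFIX[subclass]
    mark = f"{ether}-" if ether else ""
    hyd = hydroxyl or ""
    if chains:
        sep = "/" if positions_known else "_"
        body = sep.join(f"{cc}:{dd}" for cc, dd in chains)
    else:
        body = f"{c}:{db}"
    return f"{prefix}({mark}{hyd}{body})"


def print_shorthand(sh: Shorthand) -> str:
    """Inverse of :func:`parse_shorthand` on the supported grammar."""
    summary = _print_single(sh.subclass, sh.total_c, sh.total_db, (), False, sh.ether, sh.hydroxyl)
    if sh.chains:
        refined = _print_single(
            sh.subclass, sh.total_c, sh.total_db, sh.chains,
            sh.positions_known, sh.ether, sh.hydroxyl,
        )
        return f"{summary} > {refined}"
    return summary


# --- neutral formula composition rules -------------------------------------
# Each rule maps total acyl carbons c and double bonds d to (C, H, N, O, P, S)
# of the neutral species. Derived from backbone + c:d acyls minus ester
# waters; spot-checked against reference monoisotopic masses (e.g. FA 16:0
# C16H32O2 = 256.2402, PC 34:1 C42H82NO8P = 759.5778).
_RULES = {
    "FFA":    lambda c, d: (c,     2 * c - 2 * d,      0, 2,  0, 0),
    "Car":    lambda c, d: (c + 7, 2 * c - 2 * d + 13, 1, 4,  0, 0),
    "DG":     lambda c, d: (c + 3, 2 * c - 2 * d + 4,  0, 5,  0, 0),
    "TG":     lambda c, d: (c + 3, 2 * c - 2 * d + 2,  0, 6,  0, 0),
    "PA":     lambda c, d: (c + 3, 2 * c - 2 * d + 5,  0, 8,  1, 0),
    "PG":     lambda c, d: (c + 6, 2 * c - 2 * d + 11, 0, 10, 1, 0),
    "CL":     lambda c, d: (c + 9, 2 * c - 2 * d + 14, 0, 17, 2, 0),
    "LPC":    lambda c, d: (c + 8, 2 * c - 2 * d + 18, 1, 7,  1, 0),
    "LPE":    lambda c, d: (c + 5, 2 * c - 2 * d + 12, 1, 7,  1, 0),
    "PC":     lambda c, d: (c + 8, 2 * c - 2 * d + 16, 1, 8,  1, 0),
    "PE":     lambda c, d: (c + 5, 2 * c - 2 * d + 10, 1, 8,  1, 0),
    "PI":     lambda c, d: (c + 9, 2 * c - 2 * d + 15, 0, 13, 1, 0),
    "PS":     lambda c, d: (c + 6, 2 * c - 2 * d + 10, 1, 10, 1, 0),
    "Cer":    lambda c, d: (c,     2 * c - 2 * d + 1,  1, 3,  0, 0),
    "SM":     lambda c, d: (c + 5, 2 * c - 2 * d + 13, 2, 6,  1, 0),
    "HexCer": lambda c, d: (c + 6, 2 * c - 2 * d + 11, 1, 8,  0, 0),
    "SGL":    lambda c, d: (c + 6, 2 * c - 2 * d + 11, 1, 11, 0, 1),
    "SPB":    lambda c, d: (c,     2 * c - 2 * d + 3,  1, 2,  0, 0),
}


def formula_for(sh: Shorthand) -> str:
    """Neutral elemental formula (Hill order) for a parsed shorthand name."""
    c, d = sh.total_c, sh.total_db
    if sh.ether == "P":  # plasmalogen = ether + vinyl-ether double bond
        d += 1
    nC, nH, nN, nO, nP, nS = _RULES[sh.subclass](c, d)
    if sh.ether in ("O", "P"):
        nO -= 1
        nH += 2
    parts = []
    for el, n in (("C", nC), ("H", nH), ("N", nN), ("O", nO), ("P", nP), ("S", nS)):
        if n < 0:
            raise ValueError(f"composition rule gave negative {el} count for {sh}")
        if n:
            parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


# --- dictionary records ------------------------------------------------------

#: Per-subclass diagnostic fragment ions (formula of the ion, mode).
#: Head-group ions where the subclass has a classic one; fatty acids use the
#: deprotonated acyl itself, built per entry.
_SUBCLASS_FRAGMENTS: dict[str, tuple[tuple[str, str], ...]] = {
    "PC":  (("C5H15NO4P", "+"),),    # phosphocholine, 184.0733
    "LPC": (("C5H15NO4P", "+"),),
    "SM":  (("C5H15NO4P", "+"),),
    "Car": (("C4H5O2", "+"),),       # acylium-derived 85.0284
    "PE":  (("C2H7NO4P", "-"),),     # phosphoethanolamine, 140.0118
    "LPE": (("C2H7NO4P", "-"),),
    "PA":  (("C3H6O5P", "-"),),      # glycerophosphate - H2O, 152.9958
    "PG":  (("C3H6O5P", "-"),),
    "PS":  (("C3H6O5P", "-"),),
    "CL":  (("C3H6O5P", "-"),),
    "PI":  (("C6H10O8P", "-"),),     # inositol phosphate - H2O, 241.0119
    "SGL": (("HO4S", "-"),),         # hydrogensulfate, 96.9601
    "Cer": (("C18H34N", "+"),),      # dehydrated d18:1 base, 264.2686
    "HexCer": (("C18H34N", "+"),),
    "SPB": (("C18H34N", "+"),),
}

#: Allowed adducts per subclass (first listed = preferred/primary).
_SUBCLASS_ADDUCTS: dict[str, tuple[str, ...]] = {
    "Car": ("[M+H]+",),
    "FFA": ("[M-H]-",),
    "DG":  ("[M+NH4]+", "[M+Na]+"),
    "TG":  ("[M+NH4]+", "[M+Na]+"),
    "PA":  ("[M-H]-",),
    "PG":  ("[M-H]-",),
    "CL":  ("[M-H]-",),
    "LPC": ("[M+H]+", "[M+Na]+"),
    "LPE": ("[M-H]-",),
    "PC":  ("[M+H]+", "[M+Na]+"),
    "PE":  ("[M-H]-",),
    "PI":  ("[M-H]-",),
    "PS":  ("[M-H]-",),
    "Cer": ("[M+H]+",),
    "HexCer": ("[M+H]+",),
    "SGL": ("[M-H]-",),
    "SM":  ("[M+H]+",),
    "SPB": ("[M+H]+",),
}


@dataclass(frozen=True)
class LipidEntry:
    """One dictionary record: a named lipid with formula, adducts, fragments."""

    name: str
    subclass: str
    lipid_class: str
    formula: str
    adducts: tuple[str, ...]
    fragments: tuple[tuple[str, str], ...] = ()  # (ion formula, mode)

    @property
    def monoisotopic_mass(self) -> float:
        return formula_mass(self.formula)

    def adduct_mzs(self, mode: str | None = None) -> dict[str, float]:
        """Theoretical m/z per allowed adduct, optionally filtered by mode."""
        out = {}
        for label in self.adducts:
            if mode is None or ADDUCTS[label].mode == mode:
                out[label] = adduct_mz(self.monoisotopic_mass, label)
        return out


def _formula_str(comp: dict[str, int]) -> str:
    return "".join(f"{el}{n if n > 1 else ''}" for el, n in comp.items() if n)


def _entry(name: str) -> LipidEntry:
    sh = parse_shorthand(name)
    formula = formula_for(sh)
    frags = list(_SUBCLASS_FRAGMENTS.get(sh.subclass, ()))
    if sh.subclass == "FFA":
        # deprotonated fatty acid: the molecular anion minus H
        comp = dict(parse_formula(formula))
        comp["H"] -= 1
        frags = [(_formula_str(comp), "-")]
    elif sh.subclass in ("DG", "TG"):
        # no head-group ion; water loss from the protonated species
        comp = dict(parse_formula(formula))
        comp["H"] -= 1
        comp["O"] -= 1
        frags = [(_formula_str(comp), "+")]
    return LipidEntry(
        name=name,
        subclass=sh.subclass,
        lipid_class=SUBCLASS_TO_CLASS[sh.subclass],
        formula=formula,
        adducts=_SUBCLASS_ADDUCTS[sh.subclass],
        fragments=tuple(frags),
    )


@dataclass
class LipidDictionary:
    """A set of lipid entries with matching tolerances and an adduct table."""

    entries: list[LipidEntry] = field(default_factory=list)
    tolerance_ppm_precursor: float = 5.0
    tolerance_ppm_fragment: float = 10.0
    adduct_table: dict[str, Adduct] = field(default_factory=lambda: dict(ADDUCTS))

    def __post_init__(self) -> None:
        if self.tolerance_ppm_precursor <= 0 or self.tolerance_ppm_fragment <= 0:
            raise ValueError("tolerances must be positive")
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate dictionary entry names: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, name: str) -> LipidEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    # -- CSV round trip ------------------------------------------------------
    # Dialect: name,subclass,class,formula,adducts,fragment_formulas
    # adducts ';'-separated; fragments 'mode:formula' ';'-separated.

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "subclass", "class", "formula", "adducts", "fragment_formulas"])
            for e in self.entries:
                w.writerow([
                    e.name, e.subclass, e.lipid_class, e.formula,
                    ";".join(e.adducts),
                    ";".join(f"{mode}:{f}" for f, mode in e.fragments),
                ])

    @classmethod
    def read_csv(
        cls, path: str | Path,
        tolerance_ppm_precursor: float = 5.0,
        tolerance_ppm_fragment: float = 10.0,
    ) -> "LipidDictionary":
        entries = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                frags = tuple(
                    (chunk.split(":", 1)[1], chunk.split(":", 1)[0])
                    for chunk in row["fragment_formulas"].split(";")
                    if chunk
                )
                entries.append(LipidEntry(
                    name=row["name"], subclass=row["subclass"],
                    lipid_class=row["class"], formula=row["formula"],
                    adducts=tuple(a for a in row["adducts"].split(";") if a),
                    fragments=frags,
                ))
        return cls(entries, tolerance_ppm_precursor, tolerance_ppm_fragment)


# ~100 species across all 18 subclasses, including every species named in
# the cortical mTBI results this pipeline reanalyses (Car/FFA/DG/TG/PC/PE/
# PS/CL/LPE/Cer/SM species and the ether/plasmalogen PCs and PEs).
_DEFAULT_NAMES = [
    # fatty acid class
    "Car(14:0)", "Car(16:0)", "Car(16:1)", "Car(17:0)", "Car(18:1)", "Car(20:4)",
    "FA(14:0)", "FA(16:0)", "FA(16:1)", "FA(17:0)", "FA(17:1)", "FA(18:0)",
    "FA(18:1)", "FA(18:2)", "FA(18:3)", "FA(20:0)", "FA(20:4)", "FA(22:2)",
    "FA(22:4)", "FA(22:6)", "FA(23:0)", "FA(28:0)",
    # glycerolipids
    "DG(34:1)", "DG(36:1)", "DG(38:4) > DG(16:0_22:4)", "DG(40:6)",
    "PA(34:1)", "PA(36:2)", "PA(38:4)",
    "PG(34:1)", "PG(36:2)", "PG(38:4)",
    "TG(36:2)", "TG(48:1)", "TG(52:2)", "TG(52:3)", "TG(54:4)", "TG(54:5)", "TG(58:9)",
    # phospholipids
    "CL(72:6)", "CL(72:8)",
    "LPC(16:0)", "LPC(18:1)", "LPC(20:4)",
    "LPE(18:1)", "LPE(20:4)", "LPE(22:6)",
    "PC(30:0) > PC(14:0_16:0)", "PC(32:0)", "PC(34:1)", "PC(36:3)", "PC(37:3)",
    "PC(38:2) > PC(18:1_20:1)", "PC(38:4)", "PC(40:8)", "PC(41:1)", "PC(41:7)",
    "PC(O-37:5)", "PC(O-38:4)", "PC(O-38:5)",
    "PE(34:1)", "PE(36:2) > PE(18:1/18:1)", "PE(36:3) > PE(18:1_18:2)",
    "PE(38:4)", "PE(40:6)", "PE(42:10) > PE(20:4_22:6)",
    "PE(O-32:1) > PE(O-16:1/16:0)", "PE(O-36:4) > PE(O-16:1/20:3)",
    "PE(O-38:5) > PE(O-18:1/20:4)", "PE(O-40:1)", "PE(O-40:5)",
    "PE(O-40:7) > PE(O-18:2/22:5)", "PE(O-42:7) > PE(O-18:2/24:5)", "PE(P-40:4)",
    "PI(34:1)", "PI(36:4)", "PI(38:4)", "PI(40:6)",
    "PS(36:1)", "PS(38:4)", "PS(40:5)", "PS(40:6)", "PS(O-40:7) > PS(O-20:3/20:4)",
    # sphingolipids
    "Cer(d34:1)", "Cer(d36:2)", "Cer(d38:2)", "Cer(d41:0)", "Cer(d42:2)",
    "HexCer(d34:1)", "HexCer(d40:1)", "HexCer(d42:2)",
    "SGL(d34:1)", "SGL(d40:1)", "SGL(d42:2)",
    "SM(d34:1)", "SM(d36:1)", "SM(d36:2)", "SM(d38:1)", "SM(d42:2)",
    "SPB(16:1)", "SPB(18:0)", "SPB(18:1)",
]


def default_dictionary(
    tolerance_ppm_precursor: float = 5.0, tolerance_ppm_fragment: float = 10.0
) -> LipidDictionary:
    """The built-in ~100-entry dictionary spanning all 18 subclasses.

    Synthetic stand-in for an in-house annotation dictionary: entries are
    generated from the shorthand grammar and subclass composition rules, so
    formulas and fragment masses are internally consistent by construction.
    """
    return LipidDictionary(
        [_entry(n) for n in _DEFAULT_NAMES],
        tolerance_ppm_precursor,
        tolerance_ppm_fragment,
    )
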