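"""Exact-mass lipid annotation with MS2 fragment confirmation.

Features are matched against a lipid dictionary by precursor m/z under an
adduct table within a ppm tolerance; candidates are confirmed by diagnostic
fragment ions in the feature's MS2 spectrum. Confirmed annotations carry
MSI level 2 (putative annotation with spectral evidence); precursor-only
matches carry level 3. Features annotated to the same lipid species form a
sibling group for species-level intensity summation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dictionary import LipidDictionary, LipidEntry, parse_shorthand
from .features import FeatureTable
from .masses import fragment_mz, ppm_error

log = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "Candidate",
    "Annotation",
    "match_precursor",
    "confirm_fragments",
    "annotate_table",
    "write_spectra_json",
    "read_spectra_json",
]


@dataclass(frozen=True)
class Spectrum:
    """One MS2 spectrum: precursor m/z, ion mode, and fragment peaks."""

    precursor_mz: float
    mode: str  # "+" or "-"
    peaks: tuple[tuple[float, float], ...]  # (mz, intensity)

    @property
    def fragment_mzs(self) -> np.ndarray:
        return np.array([mz for mz, _ in self.peaks], dtype=float)


@dataclass(frozen=True)
class Candidate:
    entry: LipidEntry
    adduct: str
    theoretical_mz: float
    ppm: float  # signed precursor mass error


@dataclass(frozen=True)
class Annotation:
    """A feature → lipid assignment with its evidence."""

    feature_id: str
    name: str
    subclass: str
    lipid_class: str
    adduct: str
    precursor_ppm: float
    n_fragments_matched: int
    msi_level: int  # 2 (fragment-confirmed) or 3 (precursor-only)
    naming_level: str  # "species" | "fatty-acyl"
    flag: str = ""  # e.g. "precursor-only" when no spectrum was available


def match_precursor(
    mz: float, ion_mode: str | None, dictionary: LipidDictionary
) -> list[Candidate]:
    """All (entry, adduct) pairs within the precursor ppm tolerance,
    sorted by |ppm error|. ``ion_mode`` None searches both polarities."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    tol = dictionary.tolerance_ppm_precursor
    out: list[Candidate] = []
    for entry in dictionary:
        for adduct, theo in entry.adduct_mzs(mode=ion_mode).items():
            err = ppm_error(mz, theo)
            if abs(err) <= tol:
                out.append(Candidate(entry, adduct, theo, err))
    out.sort(key=lambda c: (abs(c.ppm), c.entry.name))
    return out


def confirm_fragments(
    spectrum: Spectrum | None, candidate: Candidate, dictionary: LipidDictionary
) -> tuple[int, int, str]:
    """Count diagnostic fragments present in the spectrum.

    Returns (n_matched, msi_level, flag). MSI level 2 requires at least one
    matched diagnostic fragment within the fragment ppm tolerance; with no
    spectrum the match stays precursor-only at level 3.
    """
    if spectrum is None:
        return 0, 3, "precursor-only"
    tol = dictionary.tolerance_ppm_fragment
    observed = spectrum.fragment_mzs
    n = 0
    for formula, mode in candidate.entry.fragments:
        if mode != spectrum.mode:
            continue
        theo = fragment_mz(formula, mode)
        if observed.size and np.any(np.abs(observed - theo) / theo * 1e6 <= tol):
            n += 1
    return n, (2 if n >= 1 else 3), ""


def _best(candidates_scored: list[tuple[Candidate, int, int, str]]):
    # prefer more matched fragments, then smaller |ppm|, then name
    return min(candidates_scored, key=lambda t: (-t[1], abs(t[0].ppm), t[0].entry.name))


def annotate_table(
    table: FeatureTable,
    spectra: dict[str, Spectrum] | None,
    dictionary: LipidDictionary,
    ion_modes: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Annotate every feature; returns (annotations, sibling_groups).

    ``annotations`` is a DataFrame indexed by feature_id (annotated features
    only) with name/subclass/class/adduct/ppm/msi columns. ``sibling_groups``
    maps feature_id → lipid name for every feature whose species was
    annotated more than once (isotopologues, extra adducts), ready for
    :func:`lipicyte.features.sum_sibling_features`.
    """
    spectra = spectra or {}
    ion_modes = ion_modes or {}
    rows: list[Annotation] = []
    for fid, mz in table.features["mz"].items():
        mode = ion_modes.get(fid)
        candidates = match_precursor(float(mz), mode, dictionary)
        if not candidates:
            continue
        spectrum = spectra.get(fid)
        scored = [(c, *confirm_fragments(spectrum, c, dictionary)) for c in candidates]
        cand, n_matched, msi, flag = _best(scored)
        rows.append(Annotation(
            feature_id=fid,
            name=cand.entry.name,
            subclass=cand.entry.subclass,
            lipid_class=cand.entry.lipid_class,
            adduct=cand.adduct,
            precursor_ppm=cand.ppm,
            n_fragments_matched=n_matched,
            msi_level=msi,
            naming_level=parse_shorthand(cand.entry.name).naming_level,
            flag=flag,
        ))
    ann = pd.DataFrame([vars(a) for a in rows])
    if len(ann):
        ann = ann.set_index("feature_id")
    else:
        ann = pd.DataFrame(
            columns=["name", "subclass", "lipid_class", "adduct", "precursor_ppm",
                     "n_fragments_matched", "msi_level", "naming_level", "flag"]
        )
    counts = ann.groupby("name").size() if len(ann) else pd.Series(dtype=int)
    multi = set(counts.index[counts > 1])
    sibling_groups = {
        fid: row["name"] for fid, row in ann.iterrows() if row["name"] in multi
    }
    if len(ann):
        log.info(
            "annotated %d of %d features (%d at MSI level 2) across %d subclasses",
            len(ann), table.n_features, int((ann["msi_level"] == 2).sum()),
            ann["subclass"].nunique(),
        )
    return ann, sibling_groups


# --- spectra serialization (documented JSON) --------------------------------

def write_spectra_json(spectra: dict[str, Spectrum], path: str | Path) -> None:
    obj = {
        fid: {"precursor_mz": s.precursor_mz, "mode": s.mode, "peaks": list(map(list, s.peaks))}
        for fid, s in spectra.items()
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def read_spectra_json(path: str | Path) -> dict[str, Spectrum]:
    obj = json.loads(Path(path).read_text())
    return {
        fid: Spectrum(d["precursor_mz"], d["mode"], tuple(map(tuple, d["peaks"])))
        for fid, d in obj.items()
    }
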