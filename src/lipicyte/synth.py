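"""Synthetic data generator with known ground truth.

Emulates the statistical structure of a two-batch rat cortex mTBI study:
a balanced 2 batches × {sham, 1X, 3X} × {M, F} animal grid; log-normal
baseline peak areas; a batch-shifted feature subset (storage-time effect);
injury effects concentrated in the repetitive-injury (3X) group and
predominantly decreasing; dictionary-derived m/z values with ppm-scale
mass error among uniform decoys; MS2 spectra carrying diagnostic fragments
for true lipids; and a multiplex cytokine panel with designated
pro-inflammatory analytes decreased in 3X and lipid–cytokine couplings
planted through a Gaussian copula so the target Spearman rho is scale-free.

Everything is produced post-quantification (feature tables, not
chromatograms), matching what the real pipeline consumes, and is
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import Spectrum
from .cytokines import CytokinePanel, OUT_OF_RANGE_DEFAULT, PANEL_ANALYTES
from .dictionary import LipidDictionary, default_dictionary
from .features import FeatureTable
from .masses import ADDUCTS

__all__ = ["SynthConfig", "GroundTruth", "generate_feature_table", "generate_ms2",
           "generate_cytokines", "DECREASED_ANALYTES", "COUPLED_ANALYTES"]

#: Pro-inflammatory analytes planted to decrease in the 3X group.
DECREASED_ANALYTES = ("IL-1b", "IP-10", "TNF-a", "RANTES")
#: Preferred coupling targets for planted lipid-cytokine pairs.
COUPLED_ANALYTES = ("eotaxin", "IP-10", "TNF-a")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Intensities are generated in log2 space: ``batch_shift``,
    ``injury_log_fc`` and ``noise_sd`` are in log2-intensity units
    (``injury_log_fc`` signed; negative = decrease in the injured group).
    ``ppm_noise`` is the SD of the relative mass error in ppm.
    ``rho_target`` is the planted |Spearman| for lipid-cytokine couplings.
    """

    n_features: int = 2000
    n_per_cell: int = 5            # animals per batch x injury x sex cell
    frac_batch: float = 0.10
    batch_shift: float = 1.5       # = 3 x noise_sd default
    frac_injury_3x: float = 0.05
    frac_injury_1x: float = 0.02
    injury_log_fc: float = -1.0
    frac_decrease_3x: float = 0.9
    frac_decrease_1x: float = 0.5
    noise_sd: float = 0.5
    ppm_noise: float = 2.0
    rho_target: float = 0.8
    seed: int = 0
    # structure of the planted truth
    n_truth_lipids: int | None = None     # None = every dictionary entry
    frac_siblings: float = 0.3            # truth lipids given a 2nd-adduct feature
    frac_rt_below: float = 0.05           # decoys eluting before 0.75 min
    n_coupled_lipids: int = 12
    n_coupled_cytokines: int = 3
    cytokine_effect_sd: float = 1.5       # 3X decrease of designated analytes, in SD
    decreased_analytes: tuple[str, ...] = DECREASED_ANALYTES
    n_missing_animals: int = 1            # cytokine panel animals lost (53 of 54)
    n_noise_peaks: int = 10
    baseline_log_lo: float = 14.0
    baseline_log_hi: float = 24.0

    def __post_init__(self) -> None:
        for name in ("frac_batch", "frac_injury_3x", "frac_injury_1x",
                     "frac_decrease_3x", "frac_decrease_1x", "frac_siblings",
                     "frac_rt_below"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_features", "n_per_cell"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (math.isfinite(self.noise_sd) and self.noise_sd > 0):
            raise ValueError("noise_sd must be positive and finite")
        for name in ("batch_shift", "injury_log_fc", "ppm_noise",
                     "cytokine_effect_sd", "baseline_log_lo", "baseline_log_hi"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not -1.0 < self.rho_target < 1.0:
            raise ValueError("rho_target must lie in (-1, 1)")


@dataclass
class GroundTruth:
    """What was planted, keyed by generated feature ids."""

    batch_affected: set[str] = field(default_factory=set)
    injury_affected: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    dictionary_truth: dict[str, str] = field(default_factory=dict)
    sibling_of: dict[str, str] = field(default_factory=dict)   # sibling fid -> primary fid
    feature_modes: dict[str, str] = field(default_factory=dict)
    decoy_ids: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "batch_affected": sorted(self.batch_affected),
            "injury_affected": self.injury_affected,
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "dictionary_truth": self.dictionary_truth,
            "sibling_of": self.sibling_of,
            "feature_modes": self.feature_modes,
            "decoy_ids": self.decoy_ids,
        }


def _sample_grid(n_per_cell: int) -> pd.DataFrame:
    rows = []
    for batch in (1, 2):
        for injury in ("sham", "1X", "3X"):
            for sex in ("M", "F"):
                for i in range(n_per_cell):
                    rows.append({
                        "sample_id": f"B{batch}_{injury}_{sex}{i + 1:02d}",
                        "batch": batch, "injury": injury, "sex": sex,
                    })
    return pd.DataFrame(rows).set_index("sample_id")


def generate_feature_table(
    config: SynthConfig, dictionary: LipidDictionary | None = None
) -> tuple[FeatureTable, GroundTruth]:
    """Generate a raw-scale feature table plus its ground truth.

    True lipids take their m/z from dictionary adduct masses perturbed by
    ``ppm_noise`` (a fraction get a second-adduct sibling feature of the
    same species, emulating upstream adduct grouping); decoys draw m/z
    uniformly over the instrument range and RT partly below the
    solvent-front cutoff. Intensities are log-normal with additive batch
    and injury effects in log2 space.
    """
    dictionary = dictionary if dictionary is not None else default_dictionary()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    samples = _sample_grid(config.n_per_cell)
    truth = GroundTruth()

    entries = list(dictionary)
    if config.n_truth_lipids is not None:
        entries = entries[: config.n_truth_lipids]
    if len(entries) + 1 > config.n_features:
        entries = entries[: max(config.n_features - 1, 0)]

    fids: list[str] = []
    mzs: list[float] = []
    rts: list[float] = []
    counter = 0

    def new_fid() -> str:
        nonlocal counter
        counter += 1
        return f"F{counter:05d}"

    sibling_pick = rng.random(len(entries)) < config.frac_siblings
    for entry, give_sibling in zip(entries, sibling_pick):
        adduct_mzs = entry.adduct_mzs()
        labels = list(adduct_mzs)
        rt = float(rng.uniform(1.0, 24.0))
        fid = new_fid()
        mz = adduct_mzs[labels[0]] * (1.0 + rng.normal(0.0, config.ppm_noise) * 1e-6)
        fids.append(fid)
        mzs.append(mz)
        rts.append(rt)
        truth.dictionary_truth[fid] = entry.name
        truth.feature_modes[fid] = ADDUCTS[labels[0]].mode
        if give_sibling and len(labels) > 1:
            sib = new_fid()
            mz2 = adduct_mzs[labels[1]] * (1.0 + rng.normal(0.0, config.ppm_noise) * 1e-6)
            fids.append(sib)
            mzs.append(mz2)
            rts.append(rt + float(rng.normal(0.0, 0.01)))
            truth.dictionary_truth[sib] = entry.name
            truth.feature_modes[sib] = ADDUCTS[labels[1]].mode
            truth.sibling_of[sib] = fid

    n_decoys = config.n_features - len(fids)
    if n_decoys < 0:
        raise ValueError("n_features too small for the requested truth lipids")
    for _ in range(n_decoys):
        fid = new_fid()
        fids.append(fid)
        mzs.append(float(rng.uniform(150.0, 1100.0)))
        if rng.random() < config.frac_rt_below:
            rts.append(float(rng.uniform(0.05, 0.75)))
        else:
            rts.append(float(rng.uniform(0.75, 25.0)))
        truth.decoy_ids.append(fid)
        truth.feature_modes[fid] = "+" if rng.random() < 0.5 else "-"

    n = len(fids)
    primary = [f for f in fids if f not in truth.sibling_of]

    # planted coupled lipids: primary truth features, forced 3X decrease
    truth_primaries = [f for f in primary if f in truth.dictionary_truth]
    n_coupled = min(config.n_coupled_lipids, len(truth_primaries))
    coupled = [
        str(f) for f in rng.choice(truth_primaries, size=n_coupled, replace=False)
    ] if n_coupled else []

    # batch-affected features (never the coupled lipids, so planted
    # couplings survive the sham-anchored filter)
    eligible = [f for f in primary if f not in set(coupled)]
    n_batch = round(config.frac_batch * n)
    batch_set = {
        str(f) for f in rng.choice(eligible, size=min(n_batch, len(eligible)), replace=False)
    } if n_batch else set()
    truth.batch_affected = batch_set

    # injury-affected features
    mag = abs(config.injury_log_fc)
    for fid in coupled:
        truth.injury_affected.setdefault(fid, {})["3X"] = -mag
    remaining = [f for f in eligible if f not in truth.injury_affected]
    n_3x = max(round(config.frac_injury_3x * n) - len(coupled), 0)
    pick_3x = rng.choice(remaining, size=min(n_3x, len(remaining)), replace=False) if n_3x else []
    for fid in pick_3x:
        sign = -1.0 if rng.random() < config.frac_decrease_3x else 1.0
        truth.injury_affected.setdefault(str(fid), {})["3X"] = sign * mag
    pool_1x = [f for f in eligible if "1X" not in truth.injury_affected.get(f, {})]
    n_1x = round(config.frac_injury_1x * n)
    pick_1x = rng.choice(pool_1x, size=min(n_1x, len(pool_1x)), replace=False) if n_1x else []
    for fid in pick_1x:
        sign = -1.0 if rng.random() < config.frac_decrease_1x else 1.0
        truth.injury_affected.setdefault(str(fid), {})["1X"] = sign * mag

    # siblings inherit their primary's effects (co-varying species peaks)
    for sib, prim in truth.sibling_of.items():
        if prim in truth.batch_affected:
            truth.batch_affected.add(sib)
        if prim in truth.injury_affected:
            truth.injury_affected[sib] = dict(truth.injury_affected[prim])

    # intensity matrix in log2 space
    idx = {f: i for i, f in enumerate(fids)}
    mu = rng.uniform(config.baseline_log_lo, config.baseline_log_hi, size=n)
    for sib, prim in truth.sibling_of.items():
        mu[idx[sib]] = mu[idx[prim]] + math.log2(float(rng.uniform(0.1, 0.5)))
    log2I = np.tile(mu[:, None], (1, len(samples))) \
        + rng.normal(0.0, config.noise_sd, size=(n, len(samples)))
    batch2 = (samples["batch"] == 2).to_numpy()
    for fid in truth.batch_affected:
        log2I[idx[fid], batch2] += config.batch_shift
    for fid, effects in truth.injury_affected.items():
        for group, delta in effects.items():
            log2I[idx[fid], (samples["injury"] == group).to_numpy()] += delta

    table = FeatureTable(
        features=pd.DataFrame({"mz": mzs, "rt": rts},
                              index=pd.Index(fids, name="feature_id")),
        intensities=pd.DataFrame(np.exp2(log2I),
                                 index=pd.Index(fids, name="feature_id"),
                                 columns=list(samples.index)),
        samples=samples,
    )

    # planted pairs: lipids assigned round-robin to the coupled cytokines
    in_range = [a for a in PANEL_ANALYTES if a not in OUT_OF_RANGE_DEFAULT]
    targets = [a for a in COUPLED_ANALYTES if a in in_range]
    targets += [a for a in in_range if a not in targets]
    targets = targets[: config.n_coupled_cytokines]
    for i, fid in enumerate(coupled):
        if targets:
            truth.planted_pairs.append((fid, targets[i % len(targets)], +1))
    return table, truth


def generate_ms2(
    truth: GroundTruth, dictionary: LipidDictionary, config: SynthConfig,
    table: FeatureTable | None = None,
) -> dict[str, Spectrum]:
    """MS2 spectra: truth features carry their entry's diagnostic fragments
    perturbed by ``ppm_noise`` plus uniform noise peaks; decoys get
    noise-only spectra. Precursor m/z comes from ``table`` when given."""
    from .masses import fragment_mz

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    spectra: dict[str, Spectrum] = {}
    mz_of = table.features["mz"] if table is not None else None

    def noise_peaks(upper: float) -> list[tuple[float, float]]:
        return [
            (float(rng.uniform(80.0, max(upper - 1.0, 81.0))), float(rng.uniform(0.01, 0.3)))
            for _ in range(config.n_noise_peaks)
        ]

    for fid, name in truth.dictionary_truth.items():
        try:
            entry = dictionary.get(name)
        except KeyError:
            raise KeyError(f"truth feature {fid} refers to unknown dictionary entry {name!r}")
        mode = truth.feature_modes[fid]
        precursor = float(mz_of[fid]) if mz_of is not None else max(
            entry.adduct_mzs(mode).values(), default=500.0
        )
        peaks = []
        for formula, fmode in entry.fragments:
            if fmode != mode:
                continue
            theo = fragment_mz(formula, fmode)
            peaks.append((
                theo * (1.0 + rng.normal(0.0, config.ppm_noise) * 1e-6),
                float(rng.uniform(0.3, 1.0)),
            ))
        peaks += noise_peaks(precursor)
        spectra[fid] = Spectrum(precursor, mode, tuple(sorted(peaks)))
    for fid in truth.decoy_ids:
        mode = truth.feature_modes[fid]
        precursor = float(mz_of[fid]) if mz_of is not None else 500.0
        spectra[fid] = Spectrum(precursor, mode, tuple(sorted(noise_peaks(precursor))))
    return spectra


def _normal_scores(x: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(x)
    return stats.norm.ppf((ranks - 0.5) / len(x))


def generate_cytokines(
    table: FeatureTable, truth: GroundTruth, config: SynthConfig
) -> CytokinePanel:
    """Cytokine panel with planted 3X decreases and copula couplings.

    The full 26-analyte panel is generated with 12 analytes flagged outside
    the linear range (leaving 14 analyzable). Designated pro-inflammatory
    analytes get a 3X decrease of ``cytokine_effect_sd`` latent SD units.
    Each planted pair's cytokine is coupled through a Gaussian copula to
    the mean normal-score of its partner lipids' intensities, with the
    copula correlation set by the rank-scale inversion
    a = 2·sin(π·rho/6); the marginal transform to a log-normal
    concentration is monotone, so the planted Spearman is preserved.
    ``n_missing_animals`` animals are dropped from the panel (the study
    assayed 53 of 54 cortices).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    animals = list(table.samples.index)
    if config.n_missing_animals:
        animals = animals[: len(animals) - config.n_missing_animals]
    meta = table.samples.loc[animals]
    n = len(animals)
    is_3x = (meta["injury"] == "3X").to_numpy(dtype=float)

    partners: dict[str, list[str]] = {}
    for fid, analyte, sign in truth.planted_pairs:
        partners.setdefault(analyte, []).append(fid)

    a_copula = 2.0 * math.sin(math.pi * config.rho_target / 6.0)
    a_copula = float(np.clip(a_copula, -0.999, 0.999))

    conc = {}
    for analyte in PANEL_ANALYTES:
        mu_k = float(rng.uniform(1.0, 5.0))
        sigma_k = 0.6
        if analyte in partners:
            scores = np.stack([
                _normal_scores(np.log(table.intensities.loc[fid, animals].to_numpy(dtype=float)))
                for fid in partners[analyte]
            ])
            zbar = scores.mean(axis=0)
            sd = zbar.std(ddof=0)
            zbar = zbar / sd if sd > 0 else zbar
            sign = truth.planted_pairs[
                [p[1] for p in truth.planted_pairs].index(analyte)
            ][2]
            latent = sign * a_copula * zbar \
                + math.sqrt(1.0 - a_copula ** 2) * rng.normal(0.0, 1.0, n)
        else:
            latent = rng.normal(0.0, 1.0, n)
        if analyte in config.decreased_analytes:
            latent = latent - config.cytokine_effect_sd * is_3x
        conc[analyte] = np.exp(mu_k + sigma_k * latent)

    concentrations = pd.DataFrame(conc, index=animals).T
    concentrations.index.name = "analyte"
    flags = pd.Series(
        {a: a not in OUT_OF_RANGE_DEFAULT for a in PANEL_ANALYTES}, name="in_linear_range"
    )
    return CytokinePanel(concentrations, flags, meta)
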