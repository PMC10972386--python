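"""Multiplex cytokine panel: ingestion, linear-range exclusion, per-analyte
z-scoring, and injury-effect testing.

Analytes whose bead fluorescence fell outside the assay's linear range are
excluded up front. Injury effects are tested per analyte with a
fixed-effects linear model ``concentration ~ injury (+ batch)`` and
Tukey-adjusted (studentized-range) pairwise contrasts between injury
groups; with the batch covariate disabled and complete data this reduces
exactly to one-way ANOVA with Tukey HSD. Missing animals are handled by
analyte-wise complete-case analysis.

Panel CSV dialect: header ``analyte,in_linear_range,<animal_id>,...``;
``in_linear_range`` is 0/1; empty cells denote missing animals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import anova_tukey, _tukey_sf
from .features import INJURY_GROUPS, _validate_samples

log = logging.getLogger(__name__)

__all__ = [
    "CytokinePanel",
    "read_cytokine_panel",
    "linear_range_filter",
    "zscore_by_analyte",
    "injury_effect",
]

#: Rat cytokine/chemokine multiplex panel analytes; the default
#: out-of-range set leaves the 15 analytes measurable at brain-lysate
#: protein loads (eotaxin, fractalkine, IL-1a/1b/5/6/13/17A/18, IP-10,
#: LIX, MIP-2, RANTES, TNF-a, VEGF).
PANEL_ANALYTES = (
    "EGF", "eotaxin", "fractalkine", "G-CSF", "GM-CSF", "GRO/KC", "IFN-g",
    "IL-1a", "IL-1b", "IL-2", "IL-4", "IL-5", "IL-6", "IL-10", "IL-12(p70)",
    "IL-13", "IL-17A", "IL-18", "IP-10", "Leptin", "LIX", "MCP-1", "MIP-1a",
    "MIP-2", "RANTES", "TNF-a", "VEGF",
)
OUT_OF_RANGE_DEFAULT = frozenset({
    "EGF", "G-CSF", "GM-CSF", "GRO/KC", "IFN-g", "IL-2", "IL-4", "IL-10",
    "IL-12(p70)", "Leptin", "MCP-1", "MIP-1a",
})


@dataclass
class CytokinePanel:
    """Analyte × animal concentration matrix with linear-range flags.

    ``concentrations``: DataFrame analyte × animal (assay units, NaN =
    missing animal for that analyte). ``in_linear_range``: bool Series per
    analyte. ``animals``: metadata (batch/injury/sex) indexed by animal id —
    may omit animals present in the paired feature table.
    """

    concentrations: pd.DataFrame
    in_linear_range: pd.Series
    animals: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_samples(self.animals)
        if not set(self.concentrations.columns) <= set(self.animals.index):
            extra = set(self.concentrations.columns) - set(self.animals.index)
            raise ValueError(f"animals missing from metadata: {sorted(extra)}")
        vals = self.concentrations.to_numpy()
        if np.isfinite(vals).any() and np.nanmin(vals) < 0:
            raise ValueError("negative concentrations")
        self.in_linear_range = self.in_linear_range.reindex(self.concentrations.index)
        if self.in_linear_range.isna().any():
            raise ValueError("in_linear_range flag missing for some analytes")

    @property
    def analytes(self) -> list[str]:
        return list(self.concentrations.index)

    def write_csv(self, path: str | Path) -> None:
        out = self.concentrations.copy()
        out.insert(0, "in_linear_range", self.in_linear_range.astype(int))
        out.index.name = "analyte"
        out.to_csv(path, float_format="%.10g")


def read_cytokine_panel(path: str | Path, metadata_path: str | Path) -> CytokinePanel:
    from .features import read_sample_metadata

    raw = pd.read_csv(path).set_index("analyte")
    flags = raw["in_linear_range"].astype(bool)
    conc = raw.drop(columns=["in_linear_range"]).apply(pd.to_numeric, errors="coerce")
    meta = read_sample_metadata(metadata_path)
    meta = meta.loc[[a for a in meta.index if a in conc.columns]]
    conc = conc[list(meta.index)]
    return CytokinePanel(conc, flags, meta)


def linear_range_filter(panel: CytokinePanel) -> CytokinePanel:
    """Retain only analytes measured within the assay's linear range."""
    keep = panel.in_linear_range[panel.in_linear_range].index
    if len(keep) == 0:
        log.warning("linear_range_filter: no analytes in linear range")
    log.info("linear_range_filter: %d of %d analytes retained", len(keep), len(panel.analytes))
    return replace(
        panel,
        concentrations=panel.concentrations.loc[keep],
        in_linear_range=panel.in_linear_range.loc[keep],
    )


def zscore_by_analyte(panel: CytokinePanel) -> pd.DataFrame:
    """Per-analyte z-scores across animals (heatmap rows).

    Missing values are ignored in the mean/SD and stay missing. Sample SD
    (ddof=1); a zero-SD analyte is an error.
    """
    conc = panel.concentrations
    if (conc.notna().sum(axis=1) < 2).any():
        raise ValueError("each analyte needs >=2 non-missing values to z-score")
    mean = conc.mean(axis=1)
    sd = conc.std(axis=1, ddof=1)
    if (sd == 0).any():
        zero = list(sd.index[sd == 0])
        raise ValueError(f"zero standard deviation for analytes {zero}")
    return conc.sub(mean, axis=0).div(sd, axis=0)


def _tukey_contrasts_ols(y: np.ndarray, injury: np.ndarray, batch: np.ndarray | None):
    """Pairwise injury contrasts from an OLS fit, adjusted by the
    studentized range with the model's residual df (Tukey–Kramer)."""
    import statsmodels.api as sm

    groups = [g for g in INJURY_GROUPS if g in set(injury)]
    X = np.column_stack(
        [np.ones_like(y)]
        + [(injury == g).astype(float) for g in groups[1:]]
    )
    names = ["const"] + groups[1:]
    if batch is not None and len(np.unique(batch)) > 1:
        X = np.column_stack([X, (batch == np.unique(batch)[1]).astype(float)])
        names.append("batch")
    model = sm.OLS(y, X).fit()
    df = int(model.df_resid)
    k = len(groups)
    # estimated group means at the reference batch level
    coef = dict(zip(names, model.params))
    cov = pd.DataFrame(model.cov_params(), index=names, columns=names)
    out = {}
    # contrasts oriented injured-minus-reference: (later group, earlier group)
    for a, b in combinations(groups, 2):
        vec = pd.Series(0.0, index=names)
        if b != groups[0]:
            vec[b] += 1
        if a != groups[0]:
            vec[a] -= 1
        est = float(sum(coef[n] * v for n, v in vec.items()))
        se = float(np.sqrt(vec @ cov @ vec))
        q = abs(est) / se * np.sqrt(2.0)
        p = float(_tukey_sf(k, df)(np.array([q]))[0])
        out[(b, a)] = (est, p)
    return out


def injury_effect(
    panel: CytokinePanel,
    include_batch: bool = True,
    alpha: float = 0.05,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Per-analyte injury-group contrasts with multiplicity-adjusted p.

    Returns one row per (analyte, contrast) with the contrast estimate,
    Tukey-adjusted p, group means ± SEM, direction relative to the second
    (reference) group, and a significance flag at ``alpha``. Complete-case
    per analyte; requires ≥2 animals per injury group per analyte.

    ``log_scale`` fits the model on log concentrations (multiplex
    concentrations are approximately log-normal, so this stabilizes the
    variance; the estimate is then a log-ratio). Group means/SEM are
    always reported on the concentration scale.
    """
    rows = []
    for analyte in panel.analytes:
        y_all = panel.concentrations.loc[analyte]
        ok = y_all.notna()
        y_raw = y_all[ok].to_numpy(dtype=float)
        if log_scale and (y_raw <= 0).any():
            raise ValueError(f"analyte {analyte!r}: non-positive concentration on log scale")
        y = np.log(y_raw) if log_scale else y_raw
        meta = panel.animals.loc[y_all.index[ok]]
        injury = meta["injury"].to_numpy()
        groups = [g for g in INJURY_GROUPS if g in set(injury)]
        counts = {g: int((injury == g).sum()) for g in groups}
        if len(groups) < 2 or min(counts.values()) < 2:
            raise ValueError(f"analyte {analyte!r}: need >=2 animals in >=2 injury groups")
        stats_by_group = {
            g: (float(y_raw[injury == g].mean()),
                float(y_raw[injury == g].std(ddof=1) / np.sqrt(counts[g])))
            for g in groups
        }
        model_means = {g: float(y[injury == g].mean()) for g in groups}
        use_batch = include_batch and meta["batch"].nunique() > 1
        if use_batch:
            contrasts = _tukey_contrasts_ols(y, injury, meta["batch"].to_numpy())
        else:
            _, p_tukey = anova_tukey({g: y[injury == g] for g in groups})
            # orient injured-minus-reference: flip (sham, 3X) to (3X, sham)
            contrasts = {
                (b, a): (model_means[b] - model_means[a], p)
                for (a, b), p in p_tukey.items()
            }
        for (a, b), (est, p) in contrasts.items():
            rows.append({
                "analyte": analyte,
                "contrast": f"{a} vs {b}",
                "estimate": est,
                "p_adj": p,
                "mean_" + a: stats_by_group[a][0],
                "sem_" + a: stats_by_group[a][1],
                "mean_" + b: stats_by_group[b][0],
                "sem_" + b: stats_by_group[b][1],
                "direction": "increase" if est > 0 else ("decrease" if est < 0 else "none"),
                "significant": bool(p < alpha),
            })
    return pd.DataFrame(rows)
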