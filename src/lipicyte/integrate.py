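"""Lipid–cytokine integration: Spearman correlation matrix, the dual
fold-change/correlation filter, and PCA of the selected lipid panel.

Annotated lipid intensities are rank-correlated with cytokine
concentrations across the animals shared by both datasets, restricted to
one injury contrast's animals (sham plus the injured group, so the
correlation and the fold-change criterion describe the same animals; a
pure injured-group restriction is also available). Lipids pass the dual
filter when their sham-relative fold change exceeds the magnitude
threshold and they carry at least one |rho| above the correlation
threshold; cytokines are retained when at least one lipid partner passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .batchfilter import PCADiagnostics, pca_diagnostics
from .cytokines import CytokinePanel
from .features import FeatureTable

log = logging.getLogger(__name__)

__all__ = [
    "spearman_rho",
    "CorrelationMatrix",
    "correlation_matrix",
    "IntegrationSelection",
    "dual_filter",
    "selected_lipid_pca",
]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (reported as a missing cell) when either vector is
    constant; requires ≥3 paired non-missing values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("spearman_rho requires >=3 paired non-missing values")
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class CorrelationMatrix:
    rho: pd.DataFrame      # lipids × cytokines
    n_used: pd.DataFrame   # per-cell pair count
    restriction: str       # e.g. "sham+3X", "sham+1X", "all", "3X"


def correlation_matrix(
    lipid_table: FeatureTable,
    panel: CytokinePanel,
    restrict: str = "3X",
    include_sham: bool = True,
) -> CorrelationMatrix:
    """Spearman matrix of lipid features × cytokines over shared animals.

    ``restrict`` names the injured group ("3X", "1X") or "all"; by default
    sham animals are included alongside the injured group. Cells use
    pairwise-complete animals; constant vectors give NaN cells.
    """
    if restrict == "all":
        groups = None
        label = "all"
    else:
        groups = (("sham", restrict) if include_sham else (restrict,))
        label = "+".join(groups)
    lipid_animals = set(lipid_table.sample_ids(injury=groups))
    panel_animals = {
        a for a in panel.concentrations.columns
        if groups is None or panel.animals.loc[a, "injury"] in groups
    }
    shared = [a for a in lipid_table.samples.index if a in lipid_animals & panel_animals]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared animals under restriction {label!r}")
    L = lipid_table.intensities[shared]          # lipids × animals
    C = panel.concentrations[shared]             # cytokines × animals
    rho = pd.DataFrame(index=L.index, columns=C.index, dtype=float)
    n_used = pd.DataFrame(index=L.index, columns=C.index, dtype=int)
    lvals = L.to_numpy()
    # rank lipids once; cytokines may have per-analyte missing animals
    for analyte in C.index:
        cvals = C.loc[analyte].to_numpy(dtype=float)
        ok = np.isfinite(cvals)
        n = int(ok.sum())
        if n < 3:
            rho[analyte] = np.nan
            n_used[analyte] = n
            continue
        sub = lvals[:, ok]
        r = _spearman_rows(sub, cvals[ok])
        rho[analyte] = r
        n_used[analyte] = n
    log.info(
        "correlation_matrix(%s): %d lipids x %d cytokines over %d animals",
        label, rho.shape[0], rho.shape[1], len(shared),
    )
    return CorrelationMatrix(rho, n_used, label)


def _spearman_rows(block: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman of each row of ``block`` against ``y`` (no missing values)."""
    rx = stats.rankdata(block, axis=1)
    ry = stats.rankdata(y)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum(axis=1) * (ry ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (rx @ ry) / denom
    return np.where(denom == 0, np.nan, r)


@dataclass
class IntegrationSelection:
    lipids: list[str]
    cytokines: list[str]
    pairs: pd.DataFrame  # lipid, cytokine, rho, fold_change
    fc_threshold: float
    rho_threshold: float


def dual_filter(
    matrix: CorrelationMatrix,
    diff: pd.DataFrame,
    fc_threshold: float = 1.25,
    rho_threshold: float = 0.4,
) -> IntegrationSelection:
    """Reduce the matrix to lipids with an injury-level fold change AND a
    correlated cytokine partner.

    A lipid passes when its fold change for the contrast satisfies
    FC ≥ fc_threshold or FC ≤ 1/fc_threshold and it has |rho| ≥
    rho_threshold against at least one cytokine; a cytokine is kept when at
    least one passing lipid pairs with it. Raising either threshold never
    grows the selection.
    """
    missing = set(matrix.rho.index) - set(diff.index)
    if missing:
        raise ValueError(f"matrix lipids absent from differential results: {sorted(missing)[:5]}")
    fc = diff.loc[matrix.rho.index, "fold_change"]
    fc_pass = (fc >= fc_threshold) | (fc <= 1.0 / fc_threshold)
    pairs = []
    for lipid in matrix.rho.index[fc_pass]:
        row = matrix.rho.loc[lipid]
        hits = row[row.abs() >= rho_threshold].dropna()
        for cytokine, rho in hits.items():
            pairs.append({
                "lipid": lipid, "cytokine": cytokine,
                "rho": float(rho), "fold_change": float(fc[lipid]),
            })
    pairs_df = pd.DataFrame(pairs, columns=["lipid", "cytokine", "rho", "fold_change"])
    lipids = list(dict.fromkeys(pairs_df["lipid"]))
    cytokines = [c for c in matrix.rho.columns if c in set(pairs_df["cytokine"])]
    log.info(
        "dual_filter(fc>=%g, |rho|>=%g): %d lipids, %d cytokines, %d pairs",
        fc_threshold, rho_threshold, len(lipids), len(cytokines), len(pairs_df),
    )
    return IntegrationSelection(lipids, cytokines, pairs_df, fc_threshold, rho_threshold)


def selected_lipid_pca(
    table: FeatureTable, selection: IntegrationSelection, n_components: int = 3
) -> PCADiagnostics:
    """PCA of all samples over the selected lipid panel (injury and batch
    labels attached for separation scoring)."""
    if len(selection.lipids) < 2:
        raise ValueError("selected-lipid PCA needs at least 2 lipids")
    return pca_diagnostics(table.subset_features(selection.lipids), n_components)
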