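"""Batch-effect feature removal and PCA diagnostics.

Two experimental batches run far apart in time shift a subset of features.
Rather than model-based correction, features that differ significantly
between batches are removed outright by Welch's t-test — either anchored on
the sham controls only (so injury signal cannot leak into the filter) or on
the complete dataset. PCA score plots with a per-component batch-separation
score quantify the residual batch structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .features import FeatureTable

log = logging.getLogger(__name__)

__all__ = [
    "welch_p",
    "BatchFilterReport",
    "sham_batch_filter",
    "all_sample_batch_filter",
    "PCADiagnostics",
    "pca_diagnostics",
    "batch_separation_score",
]


def welch_p(x, y) -> float:
    """Two-sided p of the unequal-variance (Welch) two-sample t-test.

    Degenerate convention for the removal filter: if both groups have zero
    variance the statistic is undefined; equal means → p=1 (feature kept),
    unequal means → p=0 (feature removed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_p requires at least 2 values per group")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        return 1.0 if x.mean() == y.mean() else 0.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def _welch_p_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized Welch p per row of two feature × sample blocks."""
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1, ddof=1) == 0.0) & (b.var(axis=1, ddof=1) == 0.0)
    if degenerate.any():
        equal = a.mean(axis=1) == b.mean(axis=1)
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


@dataclass
class BatchFilterReport:
    kept_ids: list[str]
    removed_ids: list[str]
    p_values: pd.Series
    mode: str  # "sham_only" | "all_samples"
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        removed = pd.Series(False, index=self.p_values.index)
        removed.loc[self.removed_ids] = True
        return pd.DataFrame({"p_value": self.p_values, "removed": removed})


def _batch_filter(table: FeatureTable, sample_ids_1, sample_ids_2, alpha, mode):
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    if table.log_base is None:
        raise ValueError("batch filtering operates on log-transformed intensities")
    if len(sample_ids_1) < 2 or len(sample_ids_2) < 2:
        raise ValueError(f"need >=2 samples per batch for mode={mode!r}")
    a = table.intensities[sample_ids_1].to_numpy()
    b = table.intensities[sample_ids_2].to_numpy()
    p = pd.Series(_welch_p_rows(a, b), index=table.features.index, name="p_value")
    removed = list(p.index[p < alpha])
    kept = list(p.index[p >= alpha])
    log.info(
        "batch filter (%s, alpha=%g): kept %d, removed %d of %d features",
        mode, alpha, len(kept), len(removed), table.n_features,
    )
    report = BatchFilterReport(kept, removed, p, mode, alpha)
    return table.subset_features(kept), report


def sham_batch_filter(table: FeatureTable, alpha: float = 0.05):
    """Remove features differing between sham batch 1 and sham batch 2.

    Anchoring the Welch test on sham controls only removes batch-confounded
    features without consulting (and thus without discarding) injury signal.
    All samples are retained; only features are dropped. No multiplicity
    correction: removal at raw p < alpha is the conservative direction for
    a removal filter.
    """
    sham1 = table.sample_ids(injury="sham", batch=1)
    sham2 = table.sample_ids(injury="sham", batch=2)
    return _batch_filter(table, sham1, sham2, alpha, "sham_only")


def all_sample_batch_filter(table: FeatureTable, alpha: float = 0.05):
    """Variant testing batch 1 vs batch 2 over all samples (risks removing
    biologically relevant features when injury is batch-imbalanced)."""
    b1 = table.sample_ids(batch=1)
    b2 = table.sample_ids(batch=2)
    return _batch_filter(table, b1, b2, alpha, "all_samples")


@dataclass
class PCADiagnostics:
    """Sample scores, per-component variance fractions, and grouping labels."""

    scores: pd.DataFrame           # samples × PC1..PCk
    variance_fraction: np.ndarray  # length k, non-increasing, sums <= 1
    labels: pd.DataFrame           # batch / injury / sex per sample


def pca_diagnostics(
    table: FeatureTable, n_components: int = 3, scale: bool = False
) -> PCADiagnostics:
    """Centered PCA of the sample × feature matrix.

    Unit-variance scaling is off by default: log-transformed peak areas are
    on a comparable scale and autoscaling would up-weight noise features.
    """
    X = table.intensities.to_numpy().T  # samples × features
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    n_components = min(n_components, min(X.shape) - 1) or 1
    X = X - X.mean(axis=0)
    if not np.any(X):
        raise ValueError("constant matrix: no variance to decompose")
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd == 0, 1.0, sd)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCADiagnostics(
        scores=pd.DataFrame(scores, index=table.intensities.columns, columns=cols),
        variance_fraction=pca.explained_variance_ratio_.copy(),
        labels=table.samples[["batch", "injury", "sex"]].copy(),
    )


def batch_separation_score(diag: PCADiagnostics, labels=None) -> pd.Series:
    """Per-component standardized mean difference of scores between two
    label groups (default: batch). |Cohen's d| per PC; sign-flip invariant."""
    if labels is None:
        labels = diag.labels["batch"]
    labels = pd.Series(labels, index=diag.scores.index)
    values = labels.unique()
    if len(values) != 2:
        raise ValueError(f"need exactly 2 label groups, got {list(values)}")
    a = diag.scores[labels == values[0]].to_numpy()
    b = diag.scores[labels == values[1]].to_numpy()
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (na + nb - 2)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.abs(a.mean(axis=0) - b.mean(axis=0)) / pooled
    d = np.where(np.isfinite(d), d, 0.0)
    return pd.Series(d, index=diag.scores.columns, name="separation")
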