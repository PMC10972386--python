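"""Figure rendering: volcano, PCA scores with confidence ellipses,
subclass direction bars, and the lipid-cytokine correlation heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .batchfilter import PCADiagnostics

__all__ = ["volcano_plot", "pca_plot", "subclass_bars", "correlation_heatmap"]


def volcano_plot(diff: pd.DataFrame, alpha: float, fc_threshold: float, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    x = np.log2(diff["fold_change"])
    y = -np.log10(np.clip(diff["p_tukey"], 1e-300, 1.0))
    colors = diff["volcano_class"].map({"up": "tab:red", "down": "tab:blue", "ns": "0.7"})
    ax.scatter(x, y, s=4, c=colors, linewidths=0)
    ax.axhline(-np.log10(alpha), color="k", lw=0.5, ls="--")
    for v in (np.log2(fc_threshold), -np.log2(fc_threshold)):
        ax.axvline(v, color="k", lw=0.5, ls="--")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p (Tukey)")
    n_up = int((diff["volcano_class"] == "up").sum())
    n_down = int((diff["volcano_class"] == "down").sum())
    ax.set_title(f"{diff['contrast'].iloc[0]}: {n_down} down, {n_up} up")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _confidence_ellipse(ax, xy: np.ndarray, color: str, n_sd: float = 2.4477) -> None:
    # 95% ellipse from the group score covariance (chi2_2 quantile sqrt(5.991))
    if len(xy) < 3:
        return
    cov = np.cov(xy.T)
    vals, vecs = np.linalg.eigh(cov)
    angle = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
    w, h = 2 * n_sd * np.sqrt(np.maximum(vals[::-1], 0))
    from matplotlib.patches import Ellipse
    ax.add_patch(Ellipse(xy.mean(axis=0), w, h, angle=angle,
                         fill=False, color=color, lw=1))


def pca_plot(diag: PCADiagnostics, label: str, path: str | Path,
             components: tuple[str, str] = ("PC1", "PC2")) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    cx, cy = components
    groups = diag.labels[label]
    for i, (value, ids) in enumerate(groups.groupby(groups).groups.items()):
        pts = diag.scores.loc[ids, [cx, cy]].to_numpy()
        color = f"C{i}"
        ax.scatter(pts[:, 0], pts[:, 1], s=14, color=color, label=f"{label}={value}")
        _confidence_ellipse(ax, pts, color)
    ix, iy = diag.scores.columns.get_loc(cx), diag.scores.columns.get_loc(cy)
    ax.set_xlabel(f"{cx} ({diag.variance_fraction[ix]:.1%})")
    ax.set_ylabel(f"{cy} ({diag.variance_fraction[iy]:.1%})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def subclass_bars(tally: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(tally))
    ax.bar(x - 0.2, tally["n_increased"], width=0.4, label="increased (+)", color="tab:red")
    ax.bar(x + 0.2, -tally["n_decreased"], width=0.4, label="decreased (-)", color="tab:blue")
    ax.set_xticks(x, tally.index, rotation=60, ha="right", fontsize=8)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel("lipids")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def correlation_heatmap(rho: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, max(3, 0.05 * len(rho))))
    im = ax.imshow(rho.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r",
                   vmin=-1, vmax=1, interpolation="nearest")
    ax.set_xticks(range(rho.shape[1]), rho.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_xlabel("cytokine")
    ax.set_ylabel(f"{len(rho)} lipids")
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
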