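"""End-to-end pipeline: preprocess → batch filter → annotate → sum
siblings → differential analysis → cytokines → integration.

Every stage is a pure function of its inputs and the configuration, so a
rerun with the same config and seed reproduces the outputs byte-for-byte.
The run report records the feature-count funnel (detected → RT-filtered →
batch-filtered → annotated → species → selected) and every threshold used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import batchfilter as bf
from . import cytokines as ck
from . import diffexpr as dx
from . import features as ft
from . import integrate as ig
from .annotate import Spectrum, annotate_table, read_spectra_json
from .dictionary import LipidDictionary, default_dictionary

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass
class RunConfig:
    """All paths, thresholds and mode switches for one pipeline run.

    Thresholds default to the standard analysis values: RT cutoff 0.75 min,
    α = 0.05, |FC| 1.25, |rho| 0.4, 5/10 ppm tolerances, log base 2.
    """

    features_path: str | None = None
    metadata_path: str | None = None
    panel_path: str | None = None
    spectra_path: str | None = None
    dictionary_path: str | None = None
    out_dir: str | None = None

    min_rt: float = 0.75
    log_base: float = 2.0
    pseudocount: float = 0.0
    alpha: float = 0.05
    fc_threshold: float = 1.25
    rho_threshold: float = 0.4
    ppm_precursor: float = 5.0
    ppm_fragment: float = 10.0
    batch_mode: str = "sham_only"       # or "all_samples"
    contrast: tuple[str, str] = ("3X", "sham")
    restrict: str = "3X"                # injury group for the correlation
    include_sham: bool = True
    include_batch_covariate: bool = True
    by_sex: bool = False
    figures: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 <= self.rho_threshold <= 1:
            raise ValueError("rho_threshold must be in [0, 1]")
        if self.min_rt < 0 or self.ppm_precursor <= 0 or self.ppm_fragment <= 0:
            raise ValueError("min_rt must be >= 0 and ppm tolerances positive")
        if self.batch_mode not in ("sham_only", "all_samples"):
            raise ValueError(f"unknown batch_mode {self.batch_mode!r}")


@dataclass
class RunReport:
    """Stage-by-stage funnel counts and the selections, JSON-serializable."""

    config: dict
    n_features_in: int = 0
    n_after_rt: int = 0
    n_removed_rt: int = 0
    n_after_batch: int = 0
    n_removed_batch: int = 0
    n_annotated: int = 0
    n_annotated_msi2: int = 0
    n_species: int = 0
    n_sibling_features_summed: int = 0
    volcano_up: int = 0
    volcano_down: int = 0
    n_analytes_in_range: int = 0
    significant_cytokines: list[str] = field(default_factory=list)
    selected_lipids: list[str] = field(default_factory=list)
    selected_lipid_names: list[str] = field(default_factory=list)
    selected_cytokines: list[str] = field(default_factory=list)
    pca_variance_fraction: list[float] = field(default_factory=list)
    batch_separation_before: float = 0.0
    batch_separation_after: float = 0.0

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)


def _abort(stage: str, err: Exception) -> "RuntimeError":
    return RuntimeError(f"pipeline aborted at stage {stage!r}: {err}")


def run_pipeline(
    config: RunConfig,
    table: ft.FeatureTable | None = None,
    panel: ck.CytokinePanel | None = None,
    spectra: dict[str, Spectrum] | None = None,
    dictionary: LipidDictionary | None = None,
) -> RunReport:
    """Execute all stages in order; inputs may be given as loaded objects
    or via the paths in ``config``. Intermediates are written to
    ``config.out_dir`` when set; any stage error aborts with the stage
    name and cause."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(config))

    # --- preprocess ---------------------------------------------------------
    try:
        if table is None:
            if not config.features_path or not config.metadata_path:
                raise ValueError("no feature table given (features_path/metadata_path unset)")
            table = ft.read_feature_table(config.features_path, config.metadata_path)
        if dictionary is None:
            dictionary = (
                LipidDictionary.read_csv(
                    config.dictionary_path, config.ppm_precursor, config.ppm_fragment
                )
                if config.dictionary_path
                else default_dictionary(config.ppm_precursor, config.ppm_fragment)
            )
        if spectra is None and config.spectra_path:
            spectra = read_spectra_json(config.spectra_path)
        report.n_features_in = table.n_features
        table = ft.rt_filter(table, config.min_rt)
        report.n_after_rt = table.n_features
        report.n_removed_rt = report.n_features_in - report.n_after_rt
        log_table = ft.log_transform(table, config.log_base, config.pseudocount)
    except Exception as err:
        raise _abort("preprocess", err) from err

    # --- batch filter -------------------------------------------------------
    try:
        diag_before = bf.pca_diagnostics(log_table)
        report.batch_separation_before = float(bf.batch_separation_score(diag_before).max())
        filt = bf.sham_batch_filter if config.batch_mode == "sham_only" else bf.all_sample_batch_filter
        log_table, bf_report = filt(log_table, config.alpha)
        report.n_after_batch = log_table.n_features
        report.n_removed_batch = len(bf_report.removed_ids)
        diag_after = bf.pca_diagnostics(log_table)
        report.batch_separation_after = float(bf.batch_separation_score(diag_after).max())
        report.pca_variance_fraction = [float(v) for v in diag_after.variance_fraction]
        if out_dir:
            bf_report.to_frame().to_csv(out_dir / "batch_filter.csv")
            diag_after.scores.to_csv(out_dir / "pca_scores.csv", float_format="%.6g")
    except Exception as err:
        raise _abort("batchfilter", err) from err

    # --- annotation + sibling summation -------------------------------------
    try:
        raw_table = table.subset_features(log_table.features.index)
        annotations, sibling_groups = annotate_table(raw_table, spectra, dictionary)
        report.n_annotated = len(annotations)
        report.n_annotated_msi2 = int((annotations["msi_level"] == 2).sum()) if len(annotations) else 0
        report.n_sibling_features_summed = len(sibling_groups)
        annotated_raw = raw_table.subset_features(annotations.index)
        species_raw = ft.sum_sibling_features(annotated_raw, sibling_groups)
        report.n_species = species_raw.n_features
        # species-level annotation rows (groups keep their lipid name as id)
        species_ann = annotations[~annotations.index.isin(sibling_groups)].copy()
        renamed = {}
        for name in set(sibling_groups.values()):
            member = next(f for f, g in sibling_groups.items() if g == name)
            renamed[name] = annotations.loc[member]
        species_ann = pd.concat([species_ann, pd.DataFrame(renamed).T]) if renamed else species_ann
        species_ann = species_ann.loc[[f for f in species_raw.features.index if f in species_ann.index]]
        species_log = ft.log_transform(species_raw, config.log_base, config.pseudocount)
        if out_dir:
            annotations.to_csv(out_dir / "annotations.csv")
    except Exception as err:
        raise _abort("annotate", err) from err

    # --- differential analysis ----------------------------------------------
    try:
        diff_all = dx.volcano(log_table, config.contrast, config.alpha, config.fc_threshold)
        report.volcano_up = int((diff_all["volcano_class"] == "up").sum())
        report.volcano_down = int((diff_all["volcano_class"] == "down").sum())
        diff_species = dx.volcano(species_log, config.contrast, config.alpha, config.fc_threshold)
        tally = dx.subclass_tally(species_ann, diff_species)
        if out_dir:
            diff_all.to_csv(out_dir / "volcano_all_features.csv", float_format="%.6g")
            diff_species.to_csv(out_dir / "volcano_species.csv", float_format="%.6g")
            tally.to_csv(out_dir / "subclass_tally.csv", float_format="%.6g")
    except Exception as err:
        raise _abort("diffexpr", err) from err

    # --- cytokines ----------------------------------------------------------
    try:
        if panel is None:
            if not config.panel_path:
                raise ValueError("no cytokine panel given (panel_path unset)")
            panel = ck.read_cytokine_panel(config.panel_path, config.metadata_path)
        panel = ck.linear_range_filter(panel)
        report.n_analytes_in_range = len(panel.analytes)
        cyto = ck.injury_effect(panel, config.include_batch_covariate, config.alpha)
        contrast_label = f"{config.contrast[0]} vs {config.contrast[1]}"
        hits = cyto[(cyto["contrast"] == contrast_label) & cyto["significant"]]
        report.significant_cytokines = sorted(hits["analyte"])
        if out_dir:
            cyto.to_csv(out_dir / "cytokine_effects.csv", index=False, float_format="%.6g")
            ck.zscore_by_analyte(panel).to_csv(out_dir / "cytokine_zscores.csv", float_format="%.6g")
    except Exception as err:
        raise _abort("cytokines", err) from err

    # --- integration --------------------------------------------------------
    try:
        matrix = ig.correlation_matrix(species_log, panel, config.restrict, config.include_sham)
        selection = ig.dual_filter(matrix, diff_species, config.fc_threshold, config.rho_threshold)
        report.selected_lipids = selection.lipids
        report.selected_lipid_names = [
            str(species_ann.loc[l, "name"]) if l in species_ann.index else str(l)
            for l in selection.lipids
        ]
        report.selected_cytokines = selection.cytokines
        if len(selection.lipids) >= 2:
            sel_diag = ig.selected_lipid_pca(species_log, selection)
            if out_dir:
                sel_diag.scores.to_csv(out_dir / "selected_lipid_pca.csv", float_format="%.6g")
        if out_dir:
            matrix.rho.to_csv(out_dir / "correlation_matrix.csv", float_format="%.6g")
            selection.pairs.to_csv(out_dir / "selection.csv", index=False, float_format="%.6g")
    except Exception as err:
        raise _abort("integrate", err) from err

    if config.figures and out_dir:
        try:
            from . import plots
            plots.volcano_plot(diff_all, config.alpha, config.fc_threshold,
                               out_dir / "volcano.png")
            plots.pca_plot(diag_after, "batch", out_dir / "pca_batch.png")
            plots.subclass_bars(tally, out_dir / "subclass_bars.png")
            plots.correlation_heatmap(matrix.rho, out_dir / "correlation_heatmap.png")
        except Exception as err:
            raise _abort("figures", err) from err

    if out_dir:
        (out_dir / "report.json").write_text(report.to_json())
    log.info(
        "funnel: %d -> rt %d -> batch %d -> annotated %d -> species %d -> selected %d",
        report.n_features_in, report.n_after_rt, report.n_after_batch,
        report.n_annotated, report.n_species, len(report.selected_lipids),
    )
    return report
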