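"""Feature tables: I/O, validation, retention-time filtering, log transform,
and species-level summation of sibling (isotopologue/adduct) features.

A feature is one aligned chromatographic peak, characterized by m/z and
retention time with a per-sample integrated peak area. Upstream vendor
processing (peak detection, alignment, gap filling, drift correction) is
assumed done; this module consumes the resulting table.

CSV dialects
------------
Feature table: header ``feature_id,mz,rt,<sample_id>,...``; one row per
feature, intensities as non-negative reals. Metadata:
``sample_id,batch,injury,sex`` with batch in {1,2}, injury in
{sham,1X,3X}, sex in {M,F}. ``.xlsx`` files are read with the same layout
(first sheet).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

INJURY_GROUPS = ("sham", "1X", "3X")
SEXES = ("M", "F")
BATCHES = (1, 2)

__all__ = [
    "FeatureTable",
    "read_feature_table",
    "read_sample_metadata",
    "rt_filter",
    "log_transform",
    "sum_sibling_features",
]


def _validate_samples(samples: pd.DataFrame) -> None:
    if samples.index.duplicated().any():
        raise ValueError("duplicate sample_ids in metadata")
    bad = set(samples["injury"]) - set(INJURY_GROUPS)
    if bad:
        raise ValueError(f"invalid injury labels: {sorted(bad)}")
    bad = set(samples["sex"]) - set(SEXES)
    if bad:
        raise ValueError(f"invalid sex labels: {sorted(bad)}")
    bad = set(samples["batch"]) - set(BATCHES)
    if bad:
        raise ValueError(f"invalid batch labels: {sorted(bad)}")


@dataclass
class FeatureTable:
    """Features × samples intensity matrix with per-feature m/z and RT.

    ``features``: DataFrame indexed by feature_id with columns ``mz`` (Da)
    and ``rt`` (min). ``intensities``: DataFrame feature_id × sample_id.
    ``samples``: DataFrame indexed by sample_id with ``batch``, ``injury``,
    ``sex``. ``log_base`` records an applied log transform (None = raw
    scale) so fold-change computations can invert it.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    samples: pd.DataFrame
    log_base: float | None = None
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.features.index.duplicated().any():
            dupes = self.features.index[self.features.index.duplicated()].unique()
            raise ValueError(f"duplicate feature_ids: {list(dupes[:5])}")
        _validate_samples(self.samples)
        missing = set(self.samples.index) - set(self.intensities.columns)
        if missing:
            raise ValueError(f"samples in metadata missing from table: {sorted(missing)}")
        extra = set(self.intensities.columns) - set(self.samples.index)
        if extra:
            raise ValueError(f"intensity columns missing from metadata: {sorted(extra)}")
        if not self.features.index.equals(self.intensities.index):
            raise ValueError("features and intensities indexed by different feature_ids")
        vals = self.intensities.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("non-finite intensity values")
        if self.log_base is None and (vals < 0).any():
            raise ValueError("negative intensities in a raw-scale table")
        for col in ("mz", "rt"):
            if not np.isfinite(self.features[col].to_numpy()).all():
                raise ValueError(f"non-finite {col} values")
        # keep column order aligned with metadata order
        self.intensities = self.intensities[list(self.samples.index)]

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.features.copy(), self.intensities.copy(), self.samples.copy(),
            self.log_base, self.pseudocount,
        )

    def subset_features(self, feature_ids) -> "FeatureTable":
        ids = list(feature_ids)
        return replace(
            self, features=self.features.loc[ids], intensities=self.intensities.loc[ids]
        )

    def subset_samples(self, sample_ids) -> "FeatureTable":
        ids = list(sample_ids)
        return replace(
            self, samples=self.samples.loc[ids], intensities=self.intensities[ids]
        )

    def sample_ids(self, injury=None, batch=None, sex=None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if injury is not None:
            groups = (injury,) if isinstance(injury, str) else tuple(injury)
            mask &= self.samples["injury"].isin(groups)
        if batch is not None:
            mask &= self.samples["batch"] == batch
        if sex is not None:
            mask &= self.samples["sex"] == sex
        return list(self.samples.index[mask])

    def raw_intensities(self) -> pd.DataFrame:
        """Intensities on the raw (pre-log) scale, inverting any transform."""
        if self.log_base is None:
            return self.intensities
        return self.log_base ** self.intensities - self.pseudocount

    # -- I/O -----------------------------------------------------------------

    def write_csv(self, features_path: str | Path, metadata_path: str | Path | None = None) -> None:
        out = pd.concat([self.features[["mz", "rt"]], self.intensities], axis=1)
        out.index.name = "feature_id"
        out.to_csv(features_path, float_format="%.10g")
        if metadata_path is not None:
            meta = self.samples.copy()
            meta.index.name = "sample_id"
            meta.to_csv(metadata_path)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"sample_id": str, "injury": str, "sex": str})
    required = {"sample_id", "batch", "injury", "sex"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    meta = meta.set_index("sample_id")
    meta["batch"] = meta["batch"].astype(int)
    _validate_samples(meta)
    return meta


def read_feature_table(
    path: str | Path,
    metadata_path: str | Path,
    allow_missing: bool = False,
    missing_fill: float = 0.0,
) -> FeatureTable:
    """Read and validate a feature table + sample metadata.

    Missing intensity cells ("", "NA", NaN) are an error unless
    ``allow_missing`` is set, in which case they are mapped to
    ``missing_fill`` (gap filling proper belongs upstream).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path, dtype={"feature_id": str})
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        raw = pd.read_csv(path, sep=sep, dtype={"feature_id": str})
    required = {"feature_id", "mz", "rt"}
    if not required <= set(raw.columns):
        raise ValueError(f"feature table must have columns {sorted(required)}")
    raw = raw.set_index("feature_id")
    meta = read_sample_metadata(metadata_path)
    sample_cols = [c for c in raw.columns if c not in ("mz", "rt")]
    intensities = raw[sample_cols].apply(pd.to_numeric, errors="coerce")
    if intensities.isna().any().any():
        if not allow_missing:
            bad = intensities.isna().any()
            raise ValueError(
                "non-numeric or missing intensity values in columns "
                f"{list(bad.index[bad])[:5]}; pass allow_missing=True to fill"
            )
        intensities = intensities.fillna(missing_fill)
    table = FeatureTable(raw[["mz", "rt"]].astype(float), intensities, meta)
    log.info("read feature table: %d features x %d samples", table.n_features, table.n_samples)
    return table


def rt_filter(table: FeatureTable, min_rt: float = 0.75) -> FeatureTable:
    """Drop early-eluting features (solvent front / ion suppression region).

    Retains exactly the features with rt ≥ ``min_rt`` ("below" read
    strictly, so a feature at the boundary is kept); order preserved.
    """
    if min_rt < 0:
        raise ValueError("min_rt must be >= 0")
    keep = table.features.index[table.features["rt"] >= min_rt]
    removed = table.n_features - len(keep)
    log.info("rt_filter(min_rt=%g): removed %d of %d features", min_rt, removed, table.n_features)
    return table.subset_features(keep)


def log_transform(table: FeatureTable, base: float = 2.0, pseudocount: float = 0.0) -> FeatureTable:
    """Elementwise log of intensities; the transform is recorded on the
    table so downstream fold-change computations can return to raw scale."""
    if table.log_base is not None:
        raise ValueError("table is already log-transformed")
    if base <= 1:
        raise ValueError("log base must be > 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    vals = table.intensities.to_numpy()
    if ((vals + pseudocount) <= 0).any():
        raise ValueError("zero intensity with zero pseudocount: log undefined")
    out = np.log(vals + pseudocount) / math.log(base)
    return replace(
        table,
        intensities=pd.DataFrame(out, index=table.intensities.index, columns=table.intensities.columns),
        log_base=base,
        pseudocount=pseudocount,
    )


def sum_sibling_features(table: FeatureTable, groups: dict[str, str]) -> FeatureTable:
    """Sum sibling features (isotopologues/adducts of one lipid species).

    ``groups`` maps feature_id → group_id; per group, intensities are summed
    per sample on the raw scale and the representative m/z and RT are those
    of the most intense member. Ungrouped features pass through unchanged.
    Per-sample total intensity is conserved exactly.
    """
    if table.log_base is not None:
        raise ValueError("sum siblings on the raw scale, before log transform")
    unknown = set(groups) - set(table.features.index)
    if unknown:
        raise KeyError(f"grouped feature_ids not in table: {sorted(unknown)[:5]}")

    by_group: dict[str, list[str]] = {}
    for fid, gid in groups.items():
        by_group.setdefault(gid, []).append(fid)

    new_feat_rows = []
    new_int_rows = []
    consumed: set[str] = set()
    for gid, fids in by_group.items():
        fids = [f for f in table.features.index if f in set(fids)]  # table order
        consumed.update(fids)
        summed = table.intensities.loc[fids].sum(axis=0)
        top = table.intensities.loc[fids].sum(axis=1).idxmax()
        rep = table.features.loc[top]
        new_feat_rows.append(pd.Series({"mz": rep["mz"], "rt": rep["rt"]}, name=gid))
        new_int_rows.append(summed.rename(gid))

    keep = [f for f in table.features.index if f not in consumed]
    features = pd.concat(
        [table.features.loc[keep][["mz", "rt"]], pd.DataFrame(new_feat_rows)]
    ) if new_feat_rows else table.features.loc[keep][["mz", "rt"]]
    intensities = pd.concat(
        [table.intensities.loc[keep], pd.DataFrame(new_int_rows)]
    ) if new_int_rows else table.intensities.loc[keep]
    features.index.name = table.features.index.name
    return replace(table, features=features, intensities=intensities)
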