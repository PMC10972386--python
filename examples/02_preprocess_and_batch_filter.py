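"""Retention-time filtering and sham-anchored batch-effect removal.

Features eluting before 0.75 min (solvent front) are dropped, intensities
are log2-transformed, and features that differ between the two sham
control batches by Welch's t-test are removed. The PCA batch-separation
score (standardized mean difference of sample scores between batches, per
component) shows the batch structure collapsing.
"""

from lipicyte import (
    SynthConfig, batch_separation_score, default_dictionary, log_transform,
    pca_diagnostics, rt_filter, sham_batch_filter,
)
from lipicyte.synth import generate_feature_table

config = SynthConfig(n_features=1000, frac_batch=0.10, batch_shift=1.5, seed=42)
table, truth = generate_feature_table(config, default_dictionary())

filtered_rt = rt_filter(table, min_rt=0.75)
print(f"RT filter: {table.n_features} -> {filtered_rt.n_features} features "
      f"({table.n_features - filtered_rt.n_features} eluted before 0.75 min)")

logged = log_transform(filtered_rt, base=2)
before = batch_separation_score(pca_diagnostics(logged))
kept, report = sham_batch_filter(logged, alpha=0.05)
after = batch_separation_score(pca_diagnostics(kept))

removed = set(report.removed_ids)
shifted = truth.batch_affected & set(logged.features.index)
print(f"sham-anchored Welch filter: removed {len(removed)} features at p < 0.05")
print(f"  planted batch-shifted features removed: {len(removed & shifted)}/{len(shifted)}")
print(f"  max batch-separation score before: {before.max():.2f}  after: {after.max():.2f}")
print("-> near-complete removal of the planted shift; the residual score is")
print("   what chance alone produces on batch-balanced data")
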