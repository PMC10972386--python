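# lipicyte

Integrative analysis of untargeted LC-MS lipidomics feature tables and
multiplex cytokine panels, for studies that profile both from the same
tissue — the motivating case is rat cortex after single (1X) and
repetitive (3X) closed-head mild traumatic brain injury, measured in two
experimental batches.

The package is aimed at analysts who receive post-quantification feature
tables (one row per aligned chromatographic peak: m/z, retention time,
per-sample peak areas) plus a bead-based cytokine panel, and need to get
from tens of thousands of anonymous features to a short, defensible list
of named lipids that move with injury *and* track inflammation markers.

## What it computes

Given a feature table **X** (features × samples), sample metadata
(batch ∈ {1,2}, injury ∈ {sham, 1X, 3X}, sex ∈ {M, F}) and a cytokine
panel **C** (analytes × animals):

1. **Preprocessing** — drop features with RT < 0.75 min (solvent front /
   ion suppression); log₂-transform intensities.
2. **Sham-anchored batch filter** — for each feature, Welch's unequal-
   variance t-test between sham batch 1 and sham batch 2 on log data;
   remove features with p < α = 0.05. Anchoring on shams means the filter
   never sees injury signal, so biologically relevant features are spared
   (an all-samples variant is provided for comparison). PCA score plots
   with a per-component batch-separation score (standardized mean
   difference, |d|) quantify the residual batch structure.
3. **Annotation** — exact-mass precursor matching against a lipid
   dictionary under an adduct table ([M+H]⁺, [M+NH₄]⁺, [M+Na]⁺ /
   [M−H]⁻, [M+HCOO]⁻) within 5 ppm; MS2 diagnostic-fragment confirmation
   within 10 ppm (e.g. phosphocholine m/z 184.0733 for PC/LPC/SM) assigns
   MSI level 2, precursor-only matches level 3. Shorthand names follow the
   sum-composition / fatty-acyl convention
   (`PC(38:2) > PC(18:1_20:1)`, `PE(O-16:1/20:3)`) across 18 subclasses in
   four classes. Features annotated to one species are summed on the raw
   scale.
4. **Differential analysis** — per feature, one-way ANOVA across
   sham/1X/3X on log data with Tukey HSD; the volcano classifies a feature
   up/down when the Tukey-adjusted p of the plotted contrast is < 0.05
   and the raw-scale mean ratio FC ≥ 1.25 or ≤ 1/1.25. Subclass tallies
   count lipids increasing vs decreasing.
5. **Cytokines** — exclusion of analytes outside the assay's linear
   range, per-analyte z-scores for heatmaps, and injury contrasts from a
   fixed-effects model on log concentrations (batch as optional covariate)
   with Tukey-adjusted pairwise p.
6. **Integration** — Spearman ρ between every annotated lipid and every
   cytokine over the sham + injured animals shared by both datasets; the
   dual filter keeps lipids with |FC| ≥ 1.25 **and** max |ρ| ≥ 0.4, and
   cytokines with at least one passing partner; PCA of the selected panel.

A synthetic-data generator (`lipicyte.synth`) emulates the study design —
log-normal baselines, a batch-shifted feature subset, predominantly
decreasing 3X injury effects, dictionary-derived m/z values with ppm-scale
mass error, and Gaussian-copula lipid–cytokine couplings with a target
Spearman ρ — so the whole pipeline is testable against planted ground
truth at desk scale.

## Worked example

`examples/05_full_pipeline_integration.py` generates a 1,000-feature
study with 12 planted lipids copula-coupled (|ρ| = 0.8) to 3 cytokines
and runs the full pipeline:

```
feature funnel:
  detected                 1000
  after RT >= 0.75 min     961
  after sham batch filter  823
  annotated                95 (95 at MSI level 2)
  species after summation  86
volcano 3X vs sham: 24 down, 7 up
significant cytokines (3X vs sham): ['IL-1b', 'IP-10', 'RANTES', 'TNF-a', 'eotaxin']

dual filter (|FC| >= 1.25 AND |rho| >= 0.4):
  selected lipids   (12): ['Car(17:0)', 'FA(16:1)', 'FA(28:0)', 'PA(34:1)',
                           'TG(48:1)', 'PC(41:7)', 'PS(38:4)', 'Cer(d34:1)',
                           'Cer(d36:2)', 'SGL(d34:1)', 'SM(d34:1)', 'SM(d36:2)']
  selected cytokines (5): ['eotaxin', 'IL-1b', 'IP-10', 'RANTES', 'TNF-a']
  planted lipids recovered: 11/12
```

Reading the numbers: the RT filter drops the early-eluting decoys; the
sham-anchored Welch filter removes the batch-shifted subset plus a ~5%
type-I background; ~100 features carry dictionary identities and are
confirmed at MSI level 2 by their diagnostic fragments; the volcano is
dominated by decreases (the planted 3X effects are 90% decreasing); and
the dual threshold recovers 11 of the 12 planted coupled lipids with the
designated pro-inflammatory analytes flagged as decreased after repetitive
injury.

The other examples cover each capability separately (generation,
batch filtering, annotation, differential + cytokine analysis). A thin
CLI mirrors the stages:

```sh
lipicyte synth --seed 42 --out data/
lipicyte run --config cfg.json --out results/
lipicyte batchfilter --features f.csv --meta m.csv --mode sham --alpha 0.05 --out out/
```

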