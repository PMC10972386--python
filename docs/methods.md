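# Methods

This note documents the statistical models, numerical choices and known
limitations of the pipeline, and what the synthetic-data generator does
and does not emulate.

## Data model and preprocessing

A *feature* is one aligned chromatographic peak with m/z (Da), retention
time (min), and a non-negative integrated peak area per sample. Upstream
vendor processing (peak detection, alignment, isotope/adduct grouping,
gap filling, drift correction) is assumed complete; missing cells are
therefore rejected by default (`allow_missing` maps them to a documented
fill value rather than imputing).

Features with RT below 0.75 min are removed: they co-elute with the
solvent front, where ion suppression makes quantification unreliable.
"Below" is read strictly, so a feature at exactly 0.75 min is retained.

Intensities are log-transformed before any hypothesis test (peak areas
are multiplicative). The base defaults to 2 — a |1.25|-fold change is
then |0.322| log units — and is configurable because nothing downstream
depends on it beyond interpretability. The transform is recorded on the
table so fold changes can always be computed on the raw scale; summation
of sibling features is only permitted on the raw scale (sums of logs are
meaningless) and the pipeline enforces this ordering.

## Batch-effect feature removal

Two experimental batches run far apart in time shift a subset of features
(storage time, instrument drift, animal cohort). Rather than model-based
correction (ComBat, SERRF — deliberately out of scope), confounded
features are removed: per feature, Welch's unequal-variance t-test
between the two batches on log data, removal at raw p < α = 0.05.

Two anchorings are provided. The *sham-only* filter (default) compares
sham batch 1 vs sham batch 2, so group differences caused by injury can
never contribute to removal — the test is blind to injured samples by
construction (a property the tests verify by perturbing them). The
*all-samples* variant compares complete batches and is kept for
comparison; when injury is batch-imbalanced it removes biologically
relevant features at an elevated rate.

No multiplicity correction is applied in the filter: correcting would
remove fewer features, and for a removal filter the raw-p rule is the
conservative direction. Degenerate features (zero variance in both
groups) have an undefined Welch statistic; the convention is p := 1
(kept) when means agree and p := 0 (removed) when they differ, matching
the filter's intent.

PCA diagnostics use centered, unscaled samples-as-observations PCA
(log-scale areas are already comparable; autoscaling would up-weight
noise features). Residual batch structure is quantified per component as
the absolute standardized mean difference (pooled-SD Cohen's d) of
sample scores between batches — a sign-invariant replacement for
eyeballing score plots.

## Annotation

Precursor matching: for each feature, all (dictionary entry, adduct)
pairs whose theoretical m/z lies within the precursor tolerance, ranked
by |ppm error|; ppm error = 1e6·(observed − theoretical)/theoretical.
Default tolerances are 5 ppm precursor / 10 ppm fragment — standard
working tolerances for Orbitrap acquisitions at 30,000/15,000
resolution. The adduct table ([M+H]⁺, [M+NH₄]⁺, [M+Na]⁺; [M−H]⁻,
[M+HCOO]⁻) reflects a formic-acid / ammonium-formate mobile phase.

Fragment confirmation: a candidate's diagnostic fragment ions (head-group
ions such as phosphocholine 184.0733 for PC/LPC/SM, phosphoethanolamine
140.0118 for PE/LPE, inositol-phosphate 241.0119 for PI, the deprotonated
fatty acid itself for FFA, water loss for DG/TG) are searched in the
feature's MS2 spectrum within the fragment tolerance. At least one match
assigns MSI level 2 (putative annotation with spectral evidence); a
precursor-only match is level 3 and flagged. The evidence rule is
explicit and configurable because identification-confidence practice
varies between laboratories.

Ties at equal fragment count are broken by smaller |ppm|, then
lexicographic name — deterministic by construction. Some names are
genuinely mass-degenerate: a plasmalogen P-(n:k) has the same elemental
formula as the ether O-(n:k+1) species (the vinyl-ether double bond is
hidden in the prefix), so e.g. PE(P-40:4) and PE(O-40:5) cannot be
separated by exact mass and the tie-break picks one reproducibly.

Monoisotopic masses come from an in-package 8-element table
({C,H,N,O,P,S,Na,K}, CODATA/NIST principal isotopes); ion m/z accounts
for the electron. The test suite cross-checks every formula against
pyteomics as an independent oracle.

The built-in dictionary (~100 species, all 18 subclasses: Car, FFA, DG,
PA, PG, TG, CL, LPC, LPE, PC, PE, PI, PS, Cer, HexCer, SGL, SM, sphingoid
bases) is generated programmatically from per-subclass elemental
composition rules (backbone plus total acyl carbons/double bonds, ether =
O−1/H+2). It is a synthetic stand-in for a laboratory's in-house
dictionary and can be replaced by any CSV in the documented dialect
(`name,subclass,class,formula,adducts,fragment_formulas`).

Features annotated to the same species (second adducts, isotopologues
flagged upstream) form sibling groups; their raw intensities are summed,
the representative m/z/RT taken from the most intense member, and
per-sample totals are conserved exactly.

## Differential analysis

Per feature: one-way fixed-effects ANOVA across the three injury groups
on log data, with Tukey HSD (studentized range; Tukey–Kramer for unequal
n) for the pairwise contrasts. The volcano classifies a feature for one
contrast using the Tukey-adjusted p of that contrast *extracted from the
three-group model* — not a two-group t-test — together with the
fold-change criterion. Fold change defaults to the ratio of arithmetic
means of raw intensities (a geometric-mean mode is provided, as the
convention differs between laboratories); classification requires
p < 0.05 and FC ≥ 1.25 or ≤ 1/1.25.

Numerics: evaluating the exact studentized-range survival function costs
~10 ms per point, prohibitive at 10³–10⁴ features. The implementation
builds, per (k, df), a monotone cubic (PCHIP) interpolant of log-SF on a
401-point grid over q ∈ [0, 20] and caches it; agreement with the exact
distribution is ~5×10⁻⁵ absolute (verified against `scipy.stats.tukey_hsd`
feature by feature), far inside any classification decision at α = 0.05.
The scalar `anova_tukey` entry point keeps the exact distribution.

Subclass tallies count annotated lipids with FC > 1 vs FC < 1 regardless
of significance; FC exactly 1 is excluded from the denominator and
logged. Sexes are pooled by default.

## Cytokine panel

Analytes flagged outside the assay's linear range are excluded before
any statistic (flag-driven, not name-driven — the panel composition is
whatever the assay produced). Z-scores for heatmap display are
per-analyte across animals, sample SD, missing values ignored and left
missing.

Injury effects are estimated per analyte from a fixed-effects linear
model `log(concentration) ~ injury (+ batch)` with Tukey-adjusted
pairwise contrasts computed from the model's coefficient covariance and
residual df. The log scale is used because multiplex concentrations are
approximately log-normal; the contrast estimate is then a log-ratio
(group means ± SEM are always reported on the concentration scale). The
design has no repeated measures within animal, so a mixed model would
have nothing to put in its random effect — the fixed-effects model with
an optional batch covariate is the faithful interpretation. With the
covariate disabled and complete data the procedure reduces exactly to
the ANOVA + Tukey used for the lipids (tested). Missing animals are
handled analyte-wise complete-case.

## Integration

Spearman rank correlation (average ranks for ties; constant vectors give
a missing cell) between every annotated species and every in-range
cytokine, over the animals shared by both datasets. For the "3X
analysis" the restriction is sham + 3X animals — the same animals that
define the sham-relative fold change, so the two criteria of the dual
filter describe one population; a pure injured-group mode exists. Cells
are pairwise-complete with per-cell n recorded.

The dual filter keeps lipids with |FC| ≥ 1.25 for the contrast AND at
least one |ρ| ≥ 0.4, and cytokines with ≥ 1 passing partner; the
surviving bipartite pairs are reported. Output is monotone non-increasing
in both thresholds. No significance testing or FDR is applied to the
correlation matrix — the screen is by magnitude, and the selection is
exploratory by design. PCA of the selected lipid panel carries injury
and batch labelings for separation scoring.

## Synthetic-data generator

The generator emulates the statistical structure of the motivating
study, not its raw signals:

- **Design**: 2 batches × {sham, 1X, 3X} × {M, F}, 5 animals per cell
  (60 animals; 10 per batch×injury group, matching the real study's
  8–11). One animal is dropped from the cytokine panel (the study assayed
  53 of 54 cortices).
- **Intensities**: log-normal baselines, mean log₂ intensity uniform on
  [14, 24], residual SD 0.5 log₂ units. Chosen to give realistic
  dynamic range and per-group power comparable to a real peak table.
- **Batch effect**: 10% of features shifted by +1.5 log₂ units
  (3 × noise SD) in batch 2 — large enough to dominate PC structure, as
  storage-time effects do.
- **Injury effects**: 5% of features affected in 3X with |log₂ FC| = 1,
  90% decreasing (the repetitive-injury volcano is dominated by
  decreases); 2% in 1X with an even split.
- **Masses**: true lipids take dictionary adduct m/z perturbed by
  2 ppm Gaussian error; ~30% of species get a second-adduct sibling
  feature; decoys are uniform on 150–1100 Da, with 5% eluting before
  0.75 min.
- **Cytokines**: the full multiplex panel with 12 analytes flagged
  out-of-range (leaving the 15 measurable at brain-lysate protein
  loads); log-normal marginals; four designated pro-inflammatory
  analytes (IL-1β, IP-10, TNF-α, RANTES) decreased by 1.5 latent SD in
  3X.
- **Couplings**: planted lipid–cytokine pairs are realized through a
  Gaussian copula on the rank scale: the cytokine's latent variable is
  a·z̄ + √(1−a²)·ε, where z̄ is the standardized mean normal-score of the
  partner lipids and a = 2·sin(π·ρ_target/6) inverts the rank-scale
  relation. Because the marginal transform is monotone, the planted
  Spearman target is scale-free — it survives any downstream monotone
  processing. Default ρ_target = 0.8, 12 coupled lipids round-robin on
  3 cytokines (eotaxin, IP-10, TNF-α).

Everything is bit-reproducible under a fixed seed. The generator does
**not** emulate chromatographic peak shapes, intensity-dependent
(heteroscedastic) noise, missingness, correlated co-regulation within
subclasses, or drift within a batch — so passing tests demonstrate that
the statistical machinery recovers planted structure under the stated
noise model, not that the pipeline is robust to every artifact of real
acquisitions.

Problem sizes in the test and acceptance runs (10³ features, 60 animals,
tens of replicates/seeds) are the package's desk-scale defaults; all
operations are vectorized across features and scale linearly to the
10⁴–10⁵ range of real tables.

## Known limitations

- Exact-mass annotation cannot separate isomers or mass-degenerate
  name pairs (plasmalogen/ether); identification tops out at MSI level 2.
- The batch filter discards features rather than correcting them; ~α of
  unaffected features are lost to type-I error by design.
- The dual-threshold selection is a magnitude screen without error
  control; it inherits the instability of correlation estimates at
  n ≈ 40 animals, and selected panels can retain residual batch
  structure (visible in the selected-lipid PCA).
- The cytokine model treats batch as a fixed covariate; with only two
  batches nothing more elaborate is estimable.
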