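# Methods

`epidac` analyses the response of T-cell lymphoblastic lymphoma (T-LBL)
patient-derived xenograft (PDX) cohorts to a hypomethylating agent
(decitabine). It couples five analysis layers — methylation-array profiling,
negative-binomial differential expression, gene-level integration, chromatin
compartment enrichment, and in-vivo readouts — to a seeded synthetic-cohort
generator so that every stage can be exercised and validated at desk scale,
without access to a deposited dataset.

## Methylation profiling

**Input.** Normalized beta values β ∈ [0, 1] (probes × samples) with
per-entry detection p-values; a probe manifest with 0-based half-open
coordinates, gene links (many-to-many, region class ∈ {gene_body, promoter,
enhancer}), CIMP/EpiTOC panel membership and blacklist reasons.

**QC.** Entries with detection p > 0.05 (strict) become missing; probes
flagged as multimapping, SNP-within-5-bp or meQTL are removed entirely.
QC is idempotent and logs its counts.

**Imputation.** Missing betas are imputed in probe space: each missing entry
becomes the mean of its k = 10 nearest probes (NaN-aware Euclidean distance
over shared samples; `sklearn.impute.KNNImputer` with probes as rows).
Imputed values are clipped to [0, 1]. Imputation is required only for the
mitotic-age computation; the Δβ and CIMP statistics use available cases.

**CIMP.** The CIMP methylation percentage of a sample is
100 × #{panel probes with β ≥ 0.3} / #{panel probes evaluated}. The
"methylated" cutoff of 0.3 is a configurable convention (the percentage is
insensitive to it over a wide range because panel betas are bimodal). A
sample is CIMP+ iff the percentage is strictly greater than 40.

**EpiTOC mitotic age.** The arithmetic mean beta over the EpiTOC panel
probes present on the array, a proxy for accumulated cell divisions; it lies
in [0, 1] by construction.

**Differential methylation.** Δβ = mean(treated β) − mean(vehicle β), on
available cases per probe; a probe is DM iff |Δβ| > 0.2 (strict), with
direction hypo/hyper by sign. Group means are the simplest estimator
consistent with a Δβ threshold rule; probes with no data in an arm are
excluded and counted.

## Differential expression

Median-of-ratios size factors (geometric-mean reference over genes with no
zero counts) normalise library depth. Each gene is fitted with an NB GLM
(design: intercept + group, log size-factor offset) by vectorised IRLS.
Dispersion is estimated per gene by method of moments on normalised counts
(within-group residual variance), fitted to a parametric trend
α(μ) = a₀ + a₁/μ, and shrunk toward the trend in log space with weight 0.5.
The Wald statistic on the group coefficient is referred to a t distribution
with 2(n−2) degrees of freedom: the trend pools dispersion information
across genes, so the effective residual df exceeds the per-gene n−2. This
choice keeps the empirical type-I error at α = 0.05 within [0.03, 0.07]
across dispersions 0.01–0.2 and 3–4 replicates per arm (measured by the
test suite's null simulation), where a plain normal reference is liberal
and a t on n−2 df conservative. P-values are Benjamini–Hochberg adjusted;
genes are DE at padj < 0.05. Genes with all-zero counts are excluded and
logged. Fold changes are reported as log2 of the second group over the
first.

**Sensitivity signature.** From the baseline (vehicle-only) contrast of
sensitive vs less-sensitive models: genes with |log2FC| > 1 and padj < 0.05,
ranked by ascending padj, ties by descending |log2FC|, ties by gene id, and
truncated to 70. The ranking key is a determinism convention; the filter is
the substantive rule.

## Preranked gene-set enrichment

Genes are sorted by ranking score (descending, ties broken by gene id so
results depend only on the scores). The enrichment score is the signed
extremum of the weighted Kolmogorov–Smirnov running sum with hit increments
∝ |score|¹ and uniform miss increments; exact |max|/|min| ties resolve to
the positive extremum (with a 1e-9 tolerance for floating-point stability).
The null permutes gene labels: n_perm random same-size hit sets. The
p-value is the smoothed magnitude tail, (1 + #{|null ES| ≥ |ES|}) /
(1 + n_perm) — exactly uniform under the null by exchangeability and
bounded below by 1/(n_perm+1) — and NES = ES / mean(|null ES| of the same
sign). Sets outside [5, 500] genes after intersection with the ranking are
skipped and listed.

## Integration

A gene is hypomethylated iff ≥ 1 hypomethylated DM probe links to it
(probes linking several genes count for each; region classes are tallied
separately). The per-model integration table counts DM genes and CpGs by
direction, DE genes by direction, and the joint hypomethylated-and-up /
-and-down sets (joint counts over genes present in the expression data;
methylation-only counts keep all annotated genes). The join uses the
adjusted-p DE rule by default, with a flag for raw-p joining.
Cross-model concordance returns genes present in ≥ k per-model joint sets;
k = n gives the "responds in every model" core, k = n−1 the
near-consensus list. Concordant sets are monotone decreasing in k.

## Chromatin compartments

Per-sample tracks label fixed-width bins A (active/open) or B
(inactive/closed) at 50 kb resolution. The consensus keeps a label only
under unanimity; any discordance makes the bin ambiguous, and ambiguous
bins are discarded from all downstream counting — the strictest reading of
a consensus call. Features are anchored at a single point (probe start;
gene TSS — the conventional regulatory anchor, configurable to any
coordinate column) and take the label of the containing bin; features in
ambiguous bins or outside the track are excluded.

Open-chromatin enrichment of a feature set against a background that
contains it is summarised by the relative risk

    RR = [open_f / (open_f + closed_f)] / [open_r / (open_r + closed_r)],

where the r cells are the background minus the feature set. Proportions and
RR are kept at full precision internally and rounded to 2 decimals only in
reports. RR is undefined (NaN) when a denominator vanishes.

## Pre-clinical readouts

**Absolute counts.** The bead formula is implemented exactly as published:
cells/µL = (cell events × bead volume) / (bead events × cell volume × bead
concentration). Its dimensional form (concentration in the denominator)
differs from the conventional bead-counting expression, so a `standard`
variant — (cell events / bead events) × (bead volume × concentration) /
cell volume — is offered as well; neither is asserted as the intended one.
The synthetic flow tables are generated by inverting the published form, so
either convention yields internally consistent growth ratios.

**Growth.** Normalised tumor growth = (treated day-5 mean / treated day-1
mean) / (vehicle day-5 mean / vehicle day-1 mean), on bead-corrected
counts.

**Survival.** Kaplan–Meier curves via the product-limit estimator
(lifelines); arm comparisons via the log-rank (Mantel–Cox) statistic
Σ(O−E)²-over-variance with 1 df, implemented directly and cross-checked
against lifelines in the test suite. The default p-value uses the
chi-square reference (the convention of standard survival software); a
permutation p (random label reassignments, tie-inclusive with a 1e-12
tolerance) is available and preferable at very small arm sizes, where the
chi-square approximation is rough. Times are measured from treatment
start; no multiplicity correction is applied across arm pairs, matching
per-comparison reporting practice.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions, and all randomness flows from one seed through named substreams
(annotation / beta / counts / compartments / outcomes), so identical seed +
config is byte-identical.

* **Toy genome.** One chromosome of 2,000 contiguous 50 kb bins. A bin is
  open (A) with probability 0.74; gene TSSs are uniform over bins (74% of
  genes open) while probes land in open bins with probability 0.82 —
  reproducing the array/gene open-chromatin background proportions.
* **Cohort design.** 5 models (PDX1–5) × vehicle/treated × 3–4 replicates
  (default 4). Models 1–3 form the sensitive subgroup. Per-model CIMP-panel
  methylation probabilities default to (.894, .433, .952, .897, .530),
  spanning clearly hypermethylated and intermediate-but-CIMP+ models.
* **Methylation.** Vehicle betas come from a two-component Beta mixture
  (means 0.8 / 0.1, per-sample sd 0.05). Whether a non-CIMP probe is
  methylated in a model thresholds one shared per-probe uniform draw by the
  model's propensity 0.35 + 0.3 × CIMP-probability: methylation states are
  nested across models, mitotic age co-varies with CIMP percentage, and
  "methylated in every model" is a well-defined truth set for recovery
  tests. CIMP-panel probes are per-model Bernoulli draws. Treatment shifts
  60% of non-CIMP probes by −0.25 (truncated to [0, 1]), sparing the CIMP
  panel; 1% of detection p-values fail (> 0.05); 5% of probes are
  blacklisted.
* **Expression.** Counts are NB with dispersion 0.05 around lognormal(4,
  1.2) gene means and uniform(0.7, 1.3) library factors. Less-sensitive
  models respond on a 60-gene core (|log2FC| ~ U(2, 3), 80% up) drawn from
  genes with ≥ 2 affected, everywhere-methylated linked probes; sensitive
  models add 240 extra responsive genes (|log2FC| ~ U(1, 3)) — the
  subgroup asymmetry in DE counts at similar DM counts. A 50-gene
  MYC-target set is downregulated (log2FC ~ U(−1.5, −0.5)) in treated arms
  of every model; 120 baseline genes differ between subgroups in both arms
  (the signature truth). Responsive and signature genes have base means
  floored at 30 so recovery is power-limited rather than count-limited.
* **Compartments and outcomes.** Four per-sample tracks reproduce the true
  bin label with probability 0.9. Survival times are exponential (vehicle
  scale 25 d; one/two treated cycles 40/55 d, × 1.8 in sensitive models;
  5 mice/arm; 5% censoring). Flow tables invert the bead formula around
  true day-1 concentrations of ~500 cells/µL with day-5 growth ×4
  (vehicle), ×0.5 (sensitive treated) or ×1.8 (less-sensitive treated).

**What the generator does not emulate:** probe chemistry and array
normalisation artefacts, batch effects (the real cohorts can require
excluding discordant batches), genomic sequence context, correlated
methylation blocks, Hi-C contact matrices (tracks are labels, not
matrices), and inter-mouse heterogeneity beyond NB/Beta noise. Passing
tests therefore demonstrate that the statistics recover the structure they
assume, not that they are robust to those real-data complications.

## Numerical choices and degenerate inputs

Strict inequalities at every published threshold (detection p, Δβ, CIMP
percentage, padj). Empty CIMP panels, probes missing everywhere, arms
without samples, zero-variance correlations, bead counts of zero, empty
survival arms and mismatched bin grids all raise informative errors rather
than returning silent defaults. IRLS runs ≤ 50 iterations with coefficients
clipped to ±15 on the natural-log scale; dispersions are clipped to
[1e-8, 10]. TSV/CSV floats are written at %.6g, which makes pipeline
checksums reproducible across runs.

## Problem sizes

Default analyses run on the full synthetic conditions (20,000 probes, 3,000
genes, 40 samples). Simulation-based checks use 200 genes × 50 replicate
datasets (DE null calibration), 1,000 genes with 100 true effects (recall),
500 random sets × 200 permutations (GSEA calibration), 10,000 permutations
(log-rank oracle) and 200 replicate cohorts (log-rank power); these sizes
give Monte-Carlo error comfortably below the tolerances being checked.

## Known limitations

* The DE test is a deliberately transparent NB Wald test; it does not
  reproduce any particular package's shrinkage internals, outlier
  refitting, or independent filtering, and supports only two-group designs
  (no batch covariates).
* The log-rank chi-square p is rough below ~5 events per arm; use the
  permutation mode there.
* Compartment tracks are consumed as calls; PC1-sign orientation and
  contact-matrix processing are out of scope.
* The published CIMP percentages, survival medians and integration-table
  counts of any real cohort depend on that cohort's data; the synthetic
  defaults emulate their structure, not their values.
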