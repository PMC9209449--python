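# Methods

This note documents the models, conventions and design choices behind
`epicarp`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The synthetic community model

The generator emulates a factorial epicarp survey: `F` fruit types × `S`
ripening stages × `R` replicates, each biological sample (a pooled fruit
wash) split into a spiked and a non-spiked half sharing a `pair_id`.

**Community composition.** Base phylotype abundances are log-normal
(`σ = 2`), giving the long right tail typical of fruit-surface communities
where one or two moulds dominate. Two planted effects act multiplicatively on
the expected composition:

* *fruit indicators* — `n_indicator_taxa_per_fruit` (default 10) disjoint
  phylotypes per fruit, up-weighted by `indicator_fold_change` (default 8) on
  that fruit only;
* *stage trends* — `n_stage_taxa` (default 10) phylotypes whose abundance
  scales by `stage_fold_change^±(s−1)/(S−1)` across stages, half increasing
  and half decreasing.

The *realized* community of a pair is one Dirichlet draw around the expected
composition with concentration `overdispersion × p` (default scalar 200,
i.e. clearly super-multinomial sample-to-sample variation); both halves share
it, because the two halves of a real wash contain the same cells.
`overdispersion = inf` disables the perturbation. Absolute size is
`spike_cells / spike_target_fraction` cells (≈53,000 at the defaults, so the
265-cell spike is ≈0.5%) times a mean-one log-normal factor (CV 0.25).

**Sequencing.** Each half is an independent multinomial draw at a log-normal
depth (mean 50,000 reads, CV 0.3 — per-sample depths are not observable from
the emulated study, so a typical amplicon CV is assumed).

**The internal standard.** Spiked halves contain exactly `spike_cells`
standard cells on top of any natural background. Background occurrence is
drawn per pair: with a per-fruit prevalence, Poisson-many cells scaled so the
expected read count is `background_spike_reads_mean` (default 20). Prevalence
defaults to a fruit-dependent map (`cherry: 1/24`, others `0.28`, overall
≈1 in 5 non-spiked samples) so that, at the default usability thresholds,
exactly one stratum passes the gate — the situation the analysis pipeline
must handle, where absolute quantification is only defensible for one fruit.
A scalar prevalence applies uniformly.

**What the generator does not emulate.** Read-level artefacts (chimeras, PCR
primer bias, length effects), taxon-specific DNA extraction efficiency,
spatial structure within a site, and between-replicate correlation beyond the
shared pair community. Passing tests therefore demonstrate correctness of the
estimators and tests under a clean compositional model, not robustness to
extraction or amplification bias — the live-cell standard itself assumes
extraction behaves identically across taxa.

## Spike-in quantification

Cells are estimated by the read-ratio formula
`cells_ij = reads_ij / standard_reads_j × cells_added`, which is invariant to
uniform rescaling of a sample's reads (sequencing depth cancels).

* **Usability gate.** A stratum (fruit) is usable when the standard appears
  in ≥ `min_spiked_recovery` (default 0.90) of its spiked samples and in
  ≤ `max_background_rate` (default 0.10) of its non-spiked ones. The defaults
  make a 23/24-recovered, 1/24-background stratum usable and a 12/24 one not.
* **Background correction** (default on): the paired non-spiked half's
  standard reads are subtracted from the denominator before normalising,
  since natural occurrence of the standard otherwise inflates it; pairs whose
  corrected denominator is ≤ 0 are excluded with a logged reason, as are
  spiked samples with no standard reads at all. Because counts are integers,
  the floor of one read coincides with the ≤ 0 exclusion rule.
* **Surface normalisation** divides totals by `fruits_per_sample · 4πr²`
  from the per-sample mean calliper radius — the sample-level aggregation,
  since per-fruit radii within a pool are not retained.
* **Estimator properties.** The ratio estimator carries the usual
  second-order positive bias ≈ CV²(standard reads) (≈0.4% at 250 expected
  standard reads), an order of magnitude below the per-sample sampling noise
  (SD ≈ 6–7%). The acceptance suite checks a median relative error < 15% and
  a mean signed error within a ±1.5% practical-equivalence band on 200
  ground-truthed datasets.

## CSS normalisation

Cumulative-sum scaling with an explicit quantile convention: for sample *j*
with `n⁺` positive counts, `q_j` is the `⌈l·n⁺⌉`-th smallest positive count
(default `l = 0.5`) and the scaling factor is `s_j = Σ{count ≤ q_j}`;
normalised values are `count/s_j × 1000`, optionally `log(x+1)`-transformed
(off by default, so Jaccard distances see linear abundances). The fixed
median quantile is used rather than the adaptive percentile search of the
original CSS formulation: it is deterministic, testable, and adequate for the
moderate-depth tables this package targets; ties are resolved by accumulating
*all* counts ≤ q. Zeros are preserved exactly, so presence/absence analyses
are identical before and after normalisation.

## Diversity

Richness counts positive entries; Shannon entropy is reported in nats;
Simpson is the Gini–Simpson form `1 − Σp²`. "Abundance Jaccard" is
implemented as the Ružička dissimilarity `1 − Σmin(x,y)/Σmax(x,y)` — the
quantitative extension of Jaccard, stated explicitly because software
dialects differ; it relates to Bray–Curtis by `R = 2B/(1+B)`, which the test
suite uses as an independent oracle. Binary Jaccard operates on presence.
Two all-empty vectors are defined to have distance 0 (with a warning).
Geographic distances are planar Euclidean on site coordinates in km; at the
≤19 km span of a within-county survey, curvature is negligible.

## Univariate inference

The decision tree mirrors standard practice for per-sample summaries:
Shapiro–Wilk at α = 0.05; on failure, retest after √-transform; if still
non-normal, Kruskal–Wallis (tie-corrected) with Dunn's post-hoc
(`z` from pooled rank means with tie-corrected variance) and
Benjamini–Hochberg adjustment.

The two-way ANOVA uses sequential (Type I) sums of squares computed through
explicit design-matrix projections, treatment-coded so the cumulative design
is full rank; term order follows the argument order (fruit before stage).
Effect sizes are `ω² = df_e(MS_e − MS_err)/(SS_total + MS_err)`. For two
effects sharing an error term the ω² ratio reduces to
`df_a(F_a − 1)/df_b(F_b − 1)`, so fold-difference statements can be computed
from printed F statistics alone; ratios are reported to two significant
figures. Tukey HSD uses the studentized range, optionally against the wider
model's residual mean square. Degenerate inputs (constant response) return an
explicit all-NaN F table rather than raising.

## Distance-based inference

PERMANOVA follows the Gower-centring construction: `G = J(−D²/2)J`; the SS of
each sequential term is `tr(ΔH G)` for that term's projection increment, the
pseudo-F is the term mean square over the residual mean square, and `R²` is
`SS/SS_total` (terms plus residual sum to 1; on Euclidean distances of a
univariate response the whole decomposition equals classical ANOVA exactly,
which the tests verify at 1e-8). Significance uses *free* permutation of
sample identities — the convention of the software lineage this analysis
follows — with `p = (b+1)/(m+1)`; at 10,000 permutations the attainable floor
is 1/10,001 ≈ 9.999e-5. An exact mode enumerates all `n!` permutations for
small designs and reports the enumeration p including the identity. Pairwise
post-hoc PERMANOVAs subset the distance matrix per level pair and are
BH-corrected (toggleable — whether post-hoc distance tests should be
multiplicity-corrected is a judgement call; the default is conservative).

Free permutation assumes exchangeable samples. The paired spiked/non-spiked
halves of this design share a biological wash and are *not* exchangeable
units; calibration experiments in the test suite therefore use one half per
pair. Restricted permutation schemes are out of scope.

The Mantel test correlates lower-triangle entries (Pearson) and permutes one
matrix's sample order, one-sided ("greater") by default as in distance-decay
analyses.

## Indicator and set analysis

For phylotype *i* and group *g*: specificity
`A = mean abundance in g / Σ_h mean abundance in h`, fidelity `B` = fraction
of g's samples containing the phylotype, `IndVal = √(A·B)`, reported for the
argmax group. The permutation p compares the observed best-group statistic
against label permutations (group sizes preserved in exact mode), BH-adjusted
across phylotypes. The group-size-unequalised variant is used; abundances may
be raw or CSS-normalised (the pipeline uses CSS values for A while presence
for B is unaffected, since CSS preserves zeros).

Set summaries pool presence within groups and report every Venn cell (the
cells partition the observed phylotypes), per-group unique counts, and the
core set (present in all groups) with its share of total reads.

The host-potential-index correlation is a plain Pearson r of per-fruit
aggregate abundance against one score per fruit; with the study's four fruits
it has almost no power, and the implementation warns and withholds p entirely
at n = 2. Default HPI scores are synthetic stand-ins on the published scale
with raspberry at the maximum.

## Pipeline and reproducibility

`run_pipeline` fans a single seed into per-stage substreams
(`SeedSequence.spawn`), so stages are independently reproducible and a rerun
with the same config is byte-identical in its JSON outputs. Logging goes to
stderr; results only to files. Any stage failure leaves partial outputs next
to a `FAILED` marker naming the stage. The manifest records the seed, stage
seeds, decision branches taken (transformations, excluded samples, usable
strata) — enough to re-run identically.

## Problem sizes in the test and acceptance suites

Simulation-backed checks use deliberately compact configurations chosen as
the smallest designs that exercise the relevant statistics: the shared
fixture is 2 fruits × 2 stages × 3 replicates at depth 3,000; spike-in
recovery uses the full 24-pair, depth-50,000, 0.5%-spike stratum over 200
datasets; PERMANOVA calibration uses 500 null datasets of 24 independent
samples at depth 5,000 with 999 permutations; exact-enumeration oracles use
n = 6 (720 permutations) and n = 8 (70 assignments).

## Known limitations

* Absolute quantification inherits the spike-in method's core assumption:
  equal extraction and amplification efficiency across taxa.
* Fixed-quantile CSS; no adaptive percentile, rarefaction, TSS/TMM/CLR.
* Free permutation only; no strata/blocks, no dispersion (betadisper-style)
  test, so location and dispersion effects are confounded as usual.
* Taxonomy handling is string-based on a 7-rank lineage; no tree-aware
  metrics (UniFrac) and no sequence-level classification.
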