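# epicarp

Analysis of fruit-surface (epicarp) fungal communities from ITS metabarcoding
count tables, with absolute abundance estimation from a live-cell internal
standard.

Fruit skins carry dynamic fungal communities that matter both for crop
spoilage and for insect pests: the invasive fly *Drosophila suzukii* is drawn
to volatiles of Saccharomycetales yeasts (*Hanseniaspora*, *Pichia*,
*Candida*, *Metschnikowia*, *Saccharomyces*) and repelled by *Botrytis
cinerea*. `epicarp` is for microbial ecologists who have a phylotype-by-sample
count table, a taxonomy, and a factorial sampling design (fruit type ×
ripening stage, with replicate samples split into spiked / non-spiked halves)
and want the full analysis arc:

1. **Spike-in quantification.** A known number of live cells of a foreign
   fungus (by default 265 *Plectosphaerella cucumerina* cells, ~0.5% of a
   typical wash) is added to one half of each sample before DNA extraction.
   Where the standard is reliably recovered, reads convert to cells:

   `cells_ij = reads_ij / standard_reads_j × cells_added`

   optionally correcting the denominator for the standard's natural
   occurrence in the paired non-spiked half, and normalising totals by the
   pooled fruit surface area `n · 4πr²`.
2. **Community comparison.** After removing the standard phylotype, counts
   are CSS-normalised (cumulative-sum scaling at the median of positive
   counts) and compared across factors through three biodiversity lenses:
   richness/Shannon/Simpson (two-way sequential-SS ANOVA with ω² effect
   sizes, or Kruskal–Wallis after a Shapiro–Wilk → √-transform decision
   tree), presence/absence (binary Jaccard), and relative abundance
   (quantitative Jaccard, i.e. Ružička `1 − Σmin/Σmax`).
3. **Permutation inference.** Two-way full-factorial PERMANOVA from first
   principles (Gower-centred inner products, sequential hat-matrix
   projections, pseudo-F, `p = (b+1)/(m+1)`), pairwise post-hoc PERMANOVAs
   with Benjamini–Hochberg correction, Mantel tests against geographic
   distance, and indicator-phylotype analysis
   (`IndVal = √(specificity × fidelity)` with label permutation).
4. **Synthetic ground truth.** A Dirichlet-multinomial community simulator
   reproduces the study design (4 fruits × 4 stages × 6 replicates, paired
   spiked halves, planted fruit indicators and stage trends, sparse natural
   background of the standard), so every stage is testable against known
   truth.

## Worked example

```python
import epicarp as e

config = e.RunConfig(
    output_dir="demo_run",
    simulation=e.SimulationParams(),  # the full 192-sample factorial design
    permutations=999,
    seed=7,
)
manifest = e.run_pipeline(config)
print(open("demo_run/report.md").read())
```

The run takes a few seconds and writes recovery reports, absolute-abundance
tables, CSS-normalised counts, alpha/beta diversity, PERMANOVA and indicator
results, set summaries and a markdown report. With seed 7 the report includes:

```
- **jaccard_abundance** — fruit_type: R2 = 0.101, P = 0.001 (significant);
  ripening_stage: R2 = 0.0232, P = 0.013 (significant);
  fruit_type:ripening_stage: R2 = 0.0783, P = 0.001 (significant)
  The first factor's effect (R2) was 4.4 times that of the second.

40 of 300 phylotypes significant at q < 0.05
core (present in all groups): 207 phylotypes, 99.6% of reads
```

Reading: fruit type structures the community far more strongly than ripening
stage (R² ratio 4.4), matching the simulator's planted per-fruit indicator
taxa (40 detected at FDR < 5%), while most reads belong to a core community
shared by all fruits. The recovery report flags cherry as the only stratum
where the internal standard is usable (background rate 1/24 versus ~20–40%
elsewhere), and its 24 estimated totals average ≈52,300 cells against the
simulated ≈53,000-cell washes:

```
fruit_type  n_spiked_positive  n_nonspiked_positive  usable
cherry      24                 1                     True
raspberry   24                 9                     False
```

The same stages are available piecemeal from the CLI
(`epicarp simulate | quantify | normalize | diversity | test | indicators |
sets | all`) and as library calls (`detect_standard`, `absolute_abundance`,
`css_normalize`, `distance_matrix`, `Permanova(...).fit()`,
`IndicatorAnalysis(...).fit()`, ...).

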