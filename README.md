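# spatmap

Spatiotemporal proteomics of cellular differentiation: organelle maps from
density-gradient protein correlation profiles, temporal core-proteome
statistics, and their integration — built for adipogenesis-style time
courses (SGBS, hAPC and related adipocyte models) but applicable to any
system with fractionation and time-course LFQ tables.

## Who this is for

Proteomics groups that have (a) protein-correlation-profiling (PCP)
experiments — proteins quantified across ~25 density-gradient fractions in
replicate — and (b) differentiation time courses across several cell models,
and want the complete downstream analysis as tested, scriptable code instead
of a point-and-click workflow. Every stage is also runnable on synthetic
data with known ground truth, so the machinery can be validated end to end
before touching real data.

## What it computes

**Organelle localization (spatial).** Per replicate, each protein's
fraction profile is scaled to [0, 1]; proteins whose replicate profiles
correlate negatively (Pearson < 0 in any pair) are excluded. An SVM with an
RBF kernel K(x, y) = exp(−‖x−y‖²/2σ²) (σ = 0.2, C = 8) trained on organelle
marker profiles assigns each protein a **first organelle**; marker accuracy
is reported by stratified cross-validation. A **second organelle** is
inferred by mixing the first organelle's median profile m₁ with every other
compartment's m₂ and maximizing Pearson(x, (1−α)·m₁ + α·m₂) over a grid of
mixing coefficients α ∈ [0, 1]; α = 0 means the protein is specific to a
single compartment. Two cellular states are compared protein-by-protein: a
localization change is a differing first assignment.

**Temporal statistics.** Log₂ LFQ tables are filtered for valid values,
width-adjusted (robust z per sample), and missing values are imputed from a
downshifted normal (mean m − 1.8·s, SD 0.3·s). Regulated proteins come from
one-way ANOVA (or two-group t-tests) with a pooled permutation null and
FDR-style q-values (q < 0.01). z-scored temporal profiles on the timepoints
common to all cell models define a **conserved trajectory** when every
pairwise cross-model Pearson correlation is positive. Absolute **copies per
cell** follow the histone ruler, copies = I·m_DNA·N_A / (Σ_h I_h · M), with
m_DNA = 6.5 pg. Proteins are also classed by >10-fold change or exclusivity
versus the undifferentiated state.

**Integration.** Organelle proportions of total proteome mass (first
assignments × summed intensities), Fisher over-representation and rank-based
1D annotation enrichment, proteome–transcriptome correlation (per-timepoint
Spearman, per-gene Pearson of z-profiles), and Fisher-z meta-analysis of
per-cohort correlation coefficients with fixed- or random-effects weighting.

## Worked example

```sh
spatmap demo --out demo_run --seed 7
```

simulates a two-state fractionation experiment (8 organelles, 920 proteins,
3 replicates, 25 planted relocalizations), a 4-model × 6-timepoint LFQ time
course with planted trajectory archetypes and histones, a matched
transcriptome, and four clinical cohorts — then runs every stage and prints
the summary (abridged; full output in `demo_run/summary.json`):

```
"marker_mean_cv_accuracy": 1.0,
"localization_changes": { "planted": 25, "recovered": 24, "false_positives": 0 },
"conserved_counts": { "called": 755, "true": 765, "agreement": 0.983 },
"ruler_max_rel_error": 6.0e-16,
"fold_change_remodelled_fraction": 0.130,
"omics_mean_pearson": 0.442,
"meta_pooled_rho": 0.227
```

Reading: markers cross-validate perfectly at the default noise; 24 of the
25 planted localization changes are recalled with zero false calls (all 25
at zero noise); conserved-trajectory calls agree with ground truth for 98%
of proteins; histone-ruler copy numbers reproduce the planted copies to
float precision; 13% of the proteome is remodelled >10-fold across the time
course; the realized mRNA–protein profile correlation matches the simulated
0.45 target; and the pooled cohort correlation recovers the planted ρ = 0.3
within its confidence interval.

Individual stages run the same way from TSV inputs, e.g.

```sh
spatmap simulate fractionation --spec spec.yaml --out sim/ --seed 3
spatmap pcp --table sim/pg_rep1.tsv --meta sim/pg_rep1_meta.tsv \
            --table sim/pg_rep2.tsv --meta sim/pg_rep2_meta.tsv \
            --markers sim/markers.tsv --out map/
spatmap pcp-diff mapA.tsv mapB.tsv --out changes.tsv
spatmap temporal --table pg.tsv --meta meta.tsv --out results/
spatmap integrate meta --cohorts cohorts.tsv --out meta.json
```

File formats are documented in `docs/FORMATS.md`; the scientific choices in
`docs/methods.md`.

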