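# Methods

This note records the models, defaults and numerical choices behind each
stage, what the synthetic-data generators do and do not emulate, and the
known limitations.

## Protein correlation profiling (PCP)

A protein's localization signal is the *shape* of its abundance across
density-gradient fractions, not its absolute intensity. Per protein and
replicate, intensities over fractions are min–max scaled,
x′ = (x − min)/(max − min), over the observed fractions; missing fractions
stay missing. Profiles with fewer than 3 observed fractions or constant
values are excluded with a logged reason (a constant profile has no shape
and would divide by zero). Fraction 0 is the top of the gradient (the lipid
droplet fraction); fraction order is the file order.

Replicate quality control follows the standard PCP rule: a protein is kept
only if every pairwise replicate Pearson correlation is ≥ 0. Correlations
are computed over jointly observed fractions and require at least 3 of them
— a 2-point Pearson is ±1 by construction, so a pair with fewer joint
observations counts as failing. Proteins present in fewer than two
replicates cannot be checked and pass through unfiltered.

Organelle reference profiles are fraction-wise medians over a compartment's
marker proteins and all replicates, rescaled to [0, 1] a second time.
Per-protein median profiles (used for the second-assignment search) are
built the same way.

### Missing values and the feature matrix

How missing fraction values were handled upstream of classification is an
open choice; here they become 0 only when the classifier feature matrix is
assembled — absence from a gradient region reads as "below detection
there" — and never during correlation computations, which would be biased
by zero-filling. The flag `missing_as_zero_in_features` exposes this.
Proteins missing an entire replicate are dropped from the feature matrix,
whose columns are replicate-major, fraction-minor in a declared order.

### First organelle assignment

A support-vector machine with RBF kernel K(x, y) = exp(−‖x−y‖²/(2σ²)),
σ = 0.2 and C = 8 is trained on marker rows of the concatenated-replicate
feature matrix. The σ convention (2σ² in the denominator, i.e.
gamma = 1/(2σ²) = 12.5) is pinned here because RBF parameterizations vary
between toolkits; reproducibility beats guessing another tool's convention.
Multiclass classification uses scikit-learn's SVC (one-vs-one dual with
one-vs-rest decision shaping); the reported confidence is the
pairwise-coupled (Platt) class probability of the winning compartment. Ties
break by the fixed compartment vocabulary order. Proteins whose winning
probability falls below an assignment floor — default 1/(number of
classes), i.e. no better than uniform — have no positive assignment to any
organelle and are returned unassigned. "High confidence" is probability
≥ 0.5 by default; the threshold is a config knob because no canonical value
exists. Marker accuracy is stratified 5-fold cross-validation with seeded
shuffling, reported per compartment plus the unweighted mean, with the
confusion matrix accumulated over folds. A config flag can exclude a
compartment from training and prediction per condition (e.g. peroxisomes in
preadipocytes, where they co-float with other compartments and are
unresolvable).

### Second organelle assignment (α mixing)

For a protein with first organelle m₁, the search scans every other
compartment profile m₂ and α on the grid {0, 0.05, …, 1}, scoring
r(α, m₂) = Pearson(x, (1−α)·m₁ + α·m₂) against the protein's replicate-
median profile. The maximizing (m₂, α) is returned; α is the second
compartment's contribution and α = 0 means single-compartment specific.
The 0.05 grid step balances resolution against cost and is configurable.
Ties prefer smaller α (parsimony: no second compartment unless the mixture
strictly improves), then compartment order. Degenerate (constant) mixture
vectors at a grid point are skipped. The search runs over the full [0, 1]
range; results with α > 0.5 mean the "second" compartment dominates and are
left to the caller rather than silently reassigned. Because Pearson is
affine-invariant, the second 0–1 scaling of profiles does not affect the
search.

### Localization changes

Two states' maps are compared over their shared proteins: changed = first
assignments differ; a high-confidence change additionally requires high
confidence in both maps. Counts are reported stratified by confidence.

## Temporal core-proteome statistics

All tests run on log₂ intensities; copy numbers and fold-change ratios use
the linear scale. The pre-test filter keeps proteins with ≥ 2 valid values
in at least one condition (`any-group`); the copy-number variant requires
it in every condition (`per-group`).

**Width adjustment** is a per-sample robust z: x′ = (x − median)/(IQR/1.349),
1.349 being the IQR of the standard normal. The exact variant used by
upstream GUI software is undocumented; this form is symmetric, idempotent,
and config-switchable.

**Imputation** draws each missing value i.i.d. from
Normal(m − 1.8·s, (0.3·s)²) with m, s the sample's observed mean and SD —
the standard left-censored model for below-detection missingness. Draws are
seeded and column-ordered, so runs reproduce exactly.

**Permutation ANOVA.** Per protein a one-way F statistic; the null
distribution pools permuted-label F values across all proteins (250
permutations by default), which stabilizes tail estimates at small group
sizes. q(F) = (mean permuted count of null values > F) / (observed count
≥ F), clipped to [0, 1] and monotonized so q never decreases as F grows.
The numerator is strict with a 1e−9 relative epsilon: permutations that
merely recreate the observed grouping reproduce F exactly (up to float
jitter from summation order) and carry no evidence against it. Significance
is q < 0.01. Two-group tests use Student's t with label permutations, or
matched differences with sign-flip permutations when paired (FDR 0.05 for
paired primary-sample contrasts). Degenerate (constant) proteins get F = 0,
q = 1. No s0-style variance fudge factor is applied.

**z-profiles and conserved trajectories.** Per protein and model, replicate
means per timepoint are restricted to the timepoints present in *all*
models, then z-scored across timepoints with the population-SD convention
(keeps 3-point profiles well defined; matches heatmap-style z-scoring).
A protein's trajectory is conserved when every pairwise cross-model Pearson
correlation of its z-profiles is > 0. Constant profiles are degenerate and
never conserved. "Supervised" clustering is read operationally as
agglomerative (average-linkage, Euclidean) clustering of the significant
proteins' z-profiles with a user-chosen cluster count; per-model blocks can
be composed side by side for display.

**Proteomic ruler.** copies_p = I_p · m_DNA · N_A / (Σ_h I_h · M_p), with
m_DNA = 6.5 pg (diploid human genome) and M_p the molar mass. Intensity
units cancel, so copy numbers are unit-independent; halving the histone sum
doubles every copy number by construction. Ranked copies (per sample,
descending) are z-scored per protein before clustering of significant
outliers.

**Fold-change classes** versus the undifferentiated reference: exclusive to
either state (quantified in only one), >10× up, >10× down, or other.
Ratios use un-imputed linear means — imputation exists for test validity,
not ratio estimation.

## Integration

**Organelle proportions**: per compartment, the summed replicate-mean
intensity of its first-assigned proteins as a percentage of all assigned
intensity; the unassigned mass share is reported separately. Replicate
means (not sums) make the result independent of replicate count; a flag
switches to per-condition sums.

**Enrichment.** Over-representation uses the one-sided hypergeometric upper
tail with Benjamini–Hochberg correction across tested terms; the reported
"enrichment score" is fold enrichment (k/n)/(K/N) with a >2, q < 0.1
default filter. The background defaults to the quantified proteins of the
analysis at hand, not the genome, to avoid detection bias. 1D annotation
enrichment ranks all scored proteins and scores each term
s = 2·(mean member rank − (N+1)/2)/(N − n_members) ∈ [−1, 1], with a
two-sided Wilcoxon rank-sum p and BH q; s = +1 iff members occupy the top
ranks, s ≈ 0 under exchangeability.

**Proteome–transcriptome correlation**: per shared timepoint, Spearman ρ
across shared genes of log₂ values; per gene, Pearson r of profiles over
shared timepoints (≥ 3 required).

**Meta-analysis of correlations.** Cohort correlations are pooled on the
Fisher z scale, z = atanh(r), with inverse-variance weights w = n − 3;
pooled ρ = tanh(Σwz/Σw) with a 95% normal CI and two-sided p.
DerSimonian–Laird random effects (τ² added to each cohort variance) are
available by flag; fixed effects are the default since the choice is
unsettled for this use and fixed effects are the stricter report.

## Synthetic data: what it emulates, and what it does not

The generators define the test conditions for the whole pipeline.

*Fractionation*: organelle archetypes are discretized Gaussian bumps over
25 fractions scaled to [0, 1] — matching the unimodal peaks of real
gradients without claiming their shapes. Defaults: 8 organelles with peak
centers ≥ 2 fractions apart, 40 markers each, 400 single-localized and 200
dual-localized proteins (α ∈ {0.1…0.5}), profile noise SD 0.05 (clipped
back to [0, 1] so profiles stay in the classifier's feature space), 3
replicates. Dual profiles are exact convex mixtures before noise, so the α
estimator has a closed-form truth. Intensities are profile × log-normal
amplitude; a helper rescales amplitudes to plant an exact organelle
composition. A second cellular state shares the layout (same structural
seed) with independent noise and chosen relocalizations. Not emulated:
chromatography artefacts, systematic co-fractionation beyond shared
archetypes, peptide-level effects — so classifier accuracies here are
upper bounds for real gradients.

*Time course*: 4 models × 6 timepoints × 3 replicates; per-protein log₂
copies follow base + effect × archetype shape (early / intermediate / late
/ flat, 300 proteins each; effect |N(0, 1)| + 0.5, replicate noise SD 0.3).
15% of non-flat proteins get a different archetype per model, making their
trajectories non-conserved. Intensities are copies × molar mass × cells —
i.e. already normalized tables, as the pipeline expects. Histone copies are
constant and normalized so summed histone mass per cell equals the DNA
mass, making ruler recovery exact by construction. Missingness is
left-censored: the missing probability rises logistically below a
configurable abundance-rank quantile, matching the downshifted-normal
imputation model. Not emulated: batch effects, shared-peptide protein
inference, nonlinear MS response.

*Transcriptome*: per gene, the protein z-profile (optionally shifted
earlier by a lag — mRNA leads protein) mixed with unit-variance noise at a
weight calibrated so the *expected realized* Pearson correlation equals the
target; the calibration inverts the small-sample bias
E[r] ≈ ρ − ρ(1−ρ²)/(2(n−1)) numerically. A per-gene constant baseline
tracks protein abundance so cross-gene Spearman correlations are
meaningful. *Cohorts*: bivariate normal samples at a set correlation,
summarized as Spearman r and n.

Passing tests on these data demonstrate that the algorithms recover planted
parameters under their own model assumptions; they do not certify
performance on real gradients or time courses, where archetypes are less
clean and noise is structured.

## Problem sizes and determinism

The demo and the acceptance script run at the default sizes above (~2,000
proteins for change calling, 1,000 × 10 seeds for the null-FDR check,
1,000 replicates for meta-analysis coverage, all 586k enrichment tables
with N ≤ 50), completing in well under a minute on one CPU. One global seed
fans out to per-stage seeds via a CRC32 hash of the stage name; every
random step (simulation, CV folds, imputation, permutations) derives from
it, and reruns are byte-identical.

Two calibration checks are themselves statistical tests at a stated level
and will fail for the corresponding small fraction of seeds even when the
implementation is correct: the Kolmogorov–Smirnov uniformity test of null
1D-enrichment p-values (level 0.01) and, more marginally, the 93% bound on
nominal-95% CI coverage. This is the nominal behavior of those checks, not
a defect signal on its own.

## Known limitations

- The SVM multiclass mechanism is one-vs-one with coupled probabilities
  (scikit-learn's SVC); a strict one-vs-rest decision rule would differ on
  ambiguous profiles, though not on the marker-separable regimes tested.
- The permutation count (250) bounds the resolution of extreme q-values;
  raise it for small-FDR regimes.
- The α search assumes the first assignment is the dominant compartment;
  for planted α near 0.5 the SVM may legitimately pick either organelle of
  a dual protein, and recovery is then assessed up to the α ↔ 1−α symmetry.
- Upstream normalization (median-based global scaling of LFQ output) is
  assumed done; tables on a log scale are detected only heuristically.
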