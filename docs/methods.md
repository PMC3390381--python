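# Methods

This note documents the statistical procedures implemented in `netdms`,
the assumptions behind them, the defaults and why they were chosen, what
the synthetic-data generator does and does not emulate, and the numerical
choices that a maintainer or a careful user should know about.

## Gene-level summarisation

SNPs are assigned to every gene whose body ± `flank` (default 20 000 bp,
boundaries inclusive) contains their position; a SNP inside two genes'
windows counts fully toward both (no fractional assignment). The gene-wise
P value is the minimum P over the gene's mapped SNPs, with ties broken by
the lexicographically smallest SNP id so results are order-invariant.
Coordinates are 1-based inclusive in TSV input; a BED reader converts from
0-based half-open. Chromosome names are normalised by stripping a leading
`chr` and upper-casing X/Y/MT. P values of exactly 0 or above 1 are
rejected at the I/O layer rather than clamped — clamping is the
z-transformation's job.

The min-P summary is deliberately simple but biased: a gene with more SNPs
has more chances at a small minimum, and SNP count grows with gene length.
Both confounders are carried through (`n_snps`, `gene_length`) because the
module-assessment layer corrects for exactly these.

## Node weights and module score

Gene-wise P values become node weights `z = Φ⁻¹(1 − p)` after clamping p
into `[ε, 1 − ε]` with ε = 1e−15. The clamp keeps degenerate inputs finite
while leaving any realistic GWAS minimum (~1e−8) untouched. The module
score is `Z_m = Σz_i/√k`. Only genes present in both the GWAS table and
the interaction data are kept, with edges induced on that intersection;
nodes isolated by the induction are retained (they can only form singleton
modules and fail any size-dependent reasoning downstream).

## Greedy dense module search

From each seed, the candidate pool is the neighborhood within hop distance
`d = 2` of the *current* module (recomputed after every accepted
addition). Because the new score `(z_sum + z_c)/√(k+1)` is increasing in
the candidate weight, the best candidate is simply the highest-weight gene
in the pool; ties break to the lexicographically smallest symbol, making
the search deterministic across platforms. A candidate is accepted iff
`Z_{m+1} > Z_m (1 + r)` with `r = 0.1`; when the best candidate fails, no
other can pass, and the search stops. The rule is applied literally for
negative scores, where multiplying by 1.1 *lowers* the bar; with all-equal
negative weights every module stays a singleton, but score-raising
additions are still accepted.

Two structural consequences worth knowing:

* A distance-2 candidate need not share an edge with any current member,
  so member sets are dense in score but not guaranteed edge-connected.
* The multiplicative stopping rule caps module size: once the mean member
  weight is high, the next candidate must exceed roughly 20 % of the
  accumulated weight sum, so modules over strong signal saturate at ~5–7
  members. Coverage of a larger true module comes from the union of
  overlapping modules grown from different seeds, which is exactly what
  the selection/merging stages build.

## Module assessment

**Empirical-null score P.** Module scores are median-centered and a normal
null N(δ, σ²) is fitted to their central bulk by central matching: a
quadratic is fitted to the log-histogram of the central 90 % quantile
window by count-weighted least squares (the Poisson-regression
approximation), giving `σ² = −1/(2c)` and `δ = −b/(2c)` from the fitted
`a + bx + cx²`. The signal tail therefore does not inflate the null.
A two-parameter truncated-normal MLE on a fixed central window was tried
first and abandoned: on 5000 standard-normal draws it is ill-conditioned
(δ–σ likelihood ridge) and misses σ by up to 50 %. If the central
log-density is not concave (multimodal score landscapes arise on small
synthetic networks), the fit retries on narrower windows and finally falls
back to an interquartile-range estimate (δ = 0, σ = IQR/1.349) with a
warning. Scores convert to `P(Z_m) = 1 − Φ((Z_m − median − δ)/σ)`, a
strictly decreasing transform, so the P ranking is exactly the reverse
score ranking.

**Weighted resampling (`P_GL`, `P_nSNPs`).** Network genes are binned into
deciles of the covariate (fewer bins under heavy ties); each resample
draws, without replacement, the module's per-decile gene counts, so every
resample reproduces the module's covariate profile. The decile count is
configurable.

**Topology-matched randomization (`P_topo`).** Same construction with
degree bins [0,4], (4,16], (16,64], (64,∞) — lower-inclusive, resolving
the overlap of the nominal power-of-two ranges.

**Phenotype permutation (`P_emp`).** The fixed member set is re-scored
under each column of a gene × permutation matrix of null gene-wise P
values and compared with the observed score. The matrix is supplied
externally (it requires genotype-level label shuffling) or by the
synthetic generator.

All empirical P values use the +1-corrected estimator
`P = (1 + #{null ≥ observed})/(B + 1)` with ties counting toward the
exceedance — the conservative choices; both are configurable. For a batch
of modules the resamples share one stratified pool per covariate: per bin,
B ordered without-replacement draws whose first c elements are themselves
a uniform c-subset, stored as cumulative sums. This makes per-module cost
O(B), keeps P values monotone in the observed score across modules with
the same stratum profile, and makes batch assessment independent of input
order. Where the null statistic is a significance *count* (gene- and
SNP-level replication, meta SNP-set enrichment) the resampled count is
exactly hypergeometric per stratum and is drawn as such — the identical
distribution at a fraction of the cost.

## Bi-directional selection and consensus

A module is selected in discovery iff all five P values are strictly below
their thresholds (defaults all 0.05). Evaluation re-scores the *fixed*
member set with the second study's weights; members absent from the
evaluation network are dropped with k reduced, and a module with more than
20 % dropped (configurable) is marked invalid. The evaluation-side
empirical null is fitted on the evaluation scores of **all** candidate
modules, not only the selected ones — a larger, less biased pool. A module
is final iff it passes discovery and both evaluation criteria; the two
directions' final modules are merged into a union with per-gene provenance
and induced edges.

The two evaluation criteria are strongly positively dependent (both are
monotone in the evaluation score), so their joint null pass rate is close
to the single-test level α, not α². The bias-driven false positives that
survive are modules of very long / SNP-dense genes, whose scores are
inflated in *both* studies by the shared min-P confounding; they pass the
covariate-matched resampling because a greedily optimised module also
beats covariate-matched random gene sets. At the default synthetic scale
this contributes on the order of one or two false modules per direction —
the method's honest false-discovery floor at these thresholds.

## Replication and meta-analysis

Gene-level replication counts consensus genes nominally significant
(P < 0.05) in an independent study and compares with covariate-stratified
resamples of equal size (B = 10 000); SNP-level replication does the same
with uniform draws over all genotyped SNPs. Fixed-effects meta-analysis
uses inverse-variance weights on the log-odds scale with per-study genomic
control `se ← se·√λ` (λ defaults to 1), two-sided Wald P, Cochran's Q with
χ²(k−1) heterogeneity P, and I² floored at 0. Only SNPs genotyped in all
studies are combined (no imputation), after aligning each study's alleles
to the first study's orientation (sign flips for swapped alleles, strand
complementation recognised, A/T-C/G SNPs flagged ambiguous and kept by
default, irreconcilable rows dropped with a warning).

## Enrichment

Over-representation is the upper-tail hypergeometric P over a universe
defaulting to the network genes; sets are filtered to 10–250 members
within the universe. Raw P values are Bonferroni- and BH-adjusted
(via statsmodels). The empirical layer draws B random query-sized gene
sets from the universe and reports the fraction of resamples in which the
set reaches Bonferroni-adjusted significance at 0.05 (both the threshold
and the within-resample adjustment are configurable; the choice of
adjusted-P significance inside the resampling loop was an open design
point).

## Synthetic data

The generator's defaults define the package's reference study conditions:

* **Network.** A preferential-attachment (Barabási–Albert) background on
  `n − k − 2` genes with attachment `m = 2`; the `k = 10` planted genes
  form a separate double-ring complex (each gene linked to its two nearest
  and two second-nearest ring neighbours) attached to the background
  through one bridge anchored at a low-degree, graph-peripheral gene, via
  a path of two null "adapter" genes. The tether keeps the planted complex
  outside the d = 2 horizon of the background, which emulates at desk
  scale the locality of the real ~10⁴-node interactome: in a plain
  1000-node BA graph the 2-hop ball covers a third of the graph, every
  seed's module absorbs the planted genes, and the score distribution
  degenerates — a regime the real network's size prevents. The closed-form
  edge count is exposed as `expected_edge_count`. Presets: `toy`
  (50 genes), `default` (1000 genes), `paper-scale` (10 377 genes, m = 5,
  matching the real interactome's ~5×10⁴ edges).
* **GWAS tables.** Gene lengths log-normal (median 20 kb, σ_log = 1),
  SNP counts Poisson(length × 0.5/kb, min 1) — so the min-P confounding is
  present under the null exactly as in real arrays. Null SNP z ~ N(0,1);
  planted genes' SNPs get their mean shifted by `planted_effect = 3.0`
  (direction drawn once per gene, shared across studies) in the
  signal-carrying studies (`shared_fraction` of `n_studies`, default all).
  Effects are injected at the SNP level so the min-P summary and its
  biases are exercised honestly. Betas and SEs follow the log-odds
  approximation `se = 1/√(2N·maf(1−maf))` with maf ~ U(0.05, 0.5) and
  N = 2500 samples, and P = 2Φ(−|z|), so `z = beta/se` holds to machine
  precision. Alleles and positions are shared across studies (same
  platform).
* **Permutation matrices.** Each column is a fresh global-null study with
  the same per-gene SNP counts, drawn directly from the order-statistic
  law of the minimum of s uniforms, `p = 1 − (1 − U)^{1/s}`.

Not emulated: linkage disequilibrium (SNPs are independent within genes),
population stratification, genotyping error, and real PPI clustering
structure. Passing tests therefore demonstrate the statistical machinery
and its calibration, not robustness to LD-induced dependence between a
gene's SNPs or to correlated errors between studies.

## Problem sizes and defaults

| Parameter | Default | Notes |
|---|---|---|
| flank | 20 000 bp | SNP→gene window, inclusive |
| r | 0.1 | greedy expansion rate |
| d | 2 | candidate hop distance |
| clamp ε | 1e−15 | z-transform P clamp |
| B (assessment) | 1000 | resamples / permutations per test |
| B (replication) | 10 000 | gene- and SNP-level replication |
| α (all criteria) | 0.05 | seven thresholds, all configurable |
| central window | 90 % | empirical-null fit |
| covariate strata | 10 | deciles |
| eval missing-gene cap | 20 % | above it a module's evaluation is invalid |

The calibration and recovery checks run at the `default` preset
(1000 genes, ~16 000 SNPs/study, 1000 permutations; 2000 module
evaluations for null calibration; 20 pipeline replicates for recovery) —
sizes chosen so the entire suite re-runs in well under an hour on a single
core while leaving the Monte-Carlo error of every calibrated quantity
small against its acceptance band.

## Known limitations

* Member sets are not guaranteed edge-connected (distance-2 additions).
* The empirical null is a normal approximation to a right-skewed
  distribution of greedily optimised scores; its tail rejection rate under
  the null runs slightly above nominal (~6–8 % at 0.05 in simulations).
* The covariate-matched resampling compares an optimised module against
  unoptimised random gene sets, so it has essentially no power against
  modules whose inflation comes from covariate bias *plus* greedy
  selection; the bi-directional evaluation is the effective control for
  those.
* Phenotype permutation with a fixed member set measures the signal of the
  set, not of the search procedure; the discovery-side `P_emp` is
  anti-conservative for grown modules (optimisation bias) and acts as a
  sanity filter rather than a calibrated test. The evaluation-side
  `P_emp(eval)` is the calibrated one.
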