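# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `dysreg`.

## Differential expression model

Counts are modelled per gene with a negative-binomial generalized linear
model (NB2: `var = mu + alpha * mu^2`) with a log link and a log
size-factor offset:

```
counts[g, s] ~ NB(mu_{g,s}, alpha_g),
log mu_{g,s} = x_s' beta_g + log s_s
```

- **Filtering.** Genes with a median raw count across all samples below 10
  are removed before any model fitting. The even-n median is the mean of
  the two central order statistics; the cut is strictly `< 10`, so a gene
  sitting exactly at the threshold is kept.
- **Size factors** are median-of-ratios: per sample, the median over
  all-positive genes of count / (gene's geometric mean across samples),
  rescaled to geometric mean 1. Scaling one sample's counts by *c* scales
  its factor by *c* (up to re-normalization). When nearly every gene is
  truly differential with a sign imbalance, median-of-ratios can absorb
  part of the signal into the factors and bias all fold-changes by a
  common offset; this is a known limitation of the estimator and is why
  recovery tests plant effects in a minority of genes.
- **Dispersion.** Per-gene method-of-moments on size-factor-normalized
  counts with design-cell means removed: `alpha_hat = max((s2 - mu) / mu^2,
  1e-8)` with `s2` the residual variance after projecting out the design
  (degrees-of-freedom corrected). A trend `alpha(mu) = a0 + a1 / mu` is
  fitted across genes by least squares, and the final dispersion is the
  50/50 average of the raw estimate and the trend. The shrinkage keeps
  small-n (6 vs 6) Wald tests stable; the trend captures the usual extra
  Poisson noise at low counts.
- **Fitting.** IRLS (Fisher scoring) vectorised across genes: one batched
  `p x p` solve per iteration, gradient-norm tolerance 1e-8, at most 100
  iterations. Linear predictors are clipped at ±30 to keep quasi-separated
  genes (one group all zero) finite; such genes carry a `zero_group` flag.
  Genes that fail to converge or have a singular information matrix are
  flagged, get NaN p-values, and are excluded from the BH denominator.
- **Inference.** `log2fc = beta_contrast / ln 2`, standard error from the
  inverse Fisher information at the solution, `wald = log2fc / se`,
  two-sided normal tail p-value, Benjamini–Hochberg step-up adjustment.
  No fold-change shrinkage is applied; the reported estimates are maximum
  likelihood. "Absolute fold-change greater than 2" means `|log2fc| > 1`.
  The normal reference for the Wald statistic is slightly anticonservative
  at n = 12 (null rejection rate ~0.055 at the 0.05 level in simulation);
  this is the standard trade-off of Wald inference at small n.
- **Contrasts.** Default contrasts are per-stratum, matching how such
  experiments are usually reported: the genotype contrast compares HET vs
  WT among vehicle-treated samples; the treatment contrast compares drug
  vs vehicle within HET. A joint design (`design_terms=["genotype",
  "treatment"]`) is also supported.

## Surrogate covariates

Latent sample-level structure (batches) is estimated by single-pass
residual PCA: per-gene least squares of log2 CPM on the design, then the
top-k sample-space principal components of the residual matrix, each
centered and unit-norm. This is deliberately simpler than iterated
surrogate-variable algorithms — one pass, no reweighting — and recovers a
planted binary batch with |r| > 0.99 in simulation. `k` defaults to 2. It
will underperform full SVA when latent structure is partially confounded
with the design.

## Collective dysregulation test

The observed statistic is the standardized Wilcoxon rank-sum z of the DE
p-values of set members against all other tested genes: midranks for ties,
`z = (W - n1(n+1)/2) / sd(W)` with the tie-corrected variance
`n1 n2 / 12 * ((n+1) - sum(t^3 - t) / (n(n-1)))`. Negative z means the
set's p-values sit low. When the variance is zero (all p equal) z is
defined as 0, the only symmetric choice.

The null references the same standardized statistic over `B` random
subsets of the tested genes, of the same size as the (expression-
restricted) set; standardization makes the statistic comparable across
set sizes and tie structures. The empirical p-value uses the add-one
correction `(1 + r) / (B + 1)`, so the smallest reportable value is
`1/(B+1)` (1e-4 at B = 10,000) and the p-value is never zero. Sidedness
defaults to two-sided; a one-sided "low-p-enriched" variant is available.

Random subsets are drawn over gene ids sorted lexicographically from a
generator seeded by the user's seed, so results are invariant to the row
order of the input table. Type-I calibration: across 500 null simulations
(2,000 genes, 179-member exchangeable set, B = 1,000), the test rejects at
0.05 in 5% of runs.

## Cross-contrast analyses

- **Reversal.** Shared genes are those with `padj < fdr` in both
  contrasts; "reversed" means strictly opposite log2fc signs (product
  < 0); an exactly zero estimate counts as concordant (no flip evidenced).
  No significance test is attached to the fraction — it is a descriptive
  quantity. Overlap counts against supplied gene sets are reported for
  annotation of the shared set.
- **Conditional p-value enrichment.** The primary experiment's p-values
  are stratified by conditioning-experiment significance; the strata are
  compared by a two-sample Kolmogorov–Smirnov test and returned with
  ECDFs on a fixed 101-point grid. If either stratum is empty the
  enrichment is reported as undefined rather than erroring.

## PCA and phenotype correlation

PCA input is log2(CPM + 1) over all expressed genes — not a top-variable
subset and not variance-stabilized counts — because CPM is the quantity
correlated elsewhere in the pipeline. Genes are mean-centered; no
unit-variance scaling. Scores come from the SVD of the centered matrix;
`variance_fraction_i = sigma_i^2 / sum sigma^2`. Each component is
oriented so its largest-magnitude sample score is positive: correlation
signs (e.g. PC1 vs mineralization) are convention-bound, and this pins
them run-to-run. All phenotype correlations are Pearson. Zero-variance
genes get NaN correlations and rank last. The set-vs-random correlation
enrichment reuses the permutation machinery of the dysregulation test
with mean |r(PC1)| as the statistic; ties count as extreme, so testing
the whole universe against itself gives p = 1.

## Promoter overlap

Promoters are symmetric ±`flank` (default 2,000 bp) windows around
single-base TSS records, clipped at coordinate 0; strand determines only
which genomic coordinate is the TSS. All coordinates are 0-based
half-open; overlap requires at least one shared base, so touching
intervals do not overlap. Cluster strand is ignored (TFBS cluster tracks
are unstranded). The implementation is a per-chromosome sorted sweep with
a prefix maximum of cluster ends, O((n+m) log(n+m)), verified against an
all-pairs brute-force oracle.

## Synthetic-data generator

The generator emulates a 6-vs-6 two-genotype design with an optional
drug arm:

```
counts[g,s] ~ NB(mean = mu_g * 2^(x_s b_g + d_s delta_g + batch_s gamma_g) * L_s,
                 var  = mu + alpha(mu_g) mu^2)
```

Defaults and rationale:

- `mu_g` lognormal with ln-mean log(100) and ln-sd 1 — a bulk-like mean
  distribution centered on moderately expressed genes.
- Dispersion trend `alpha(mu) = 0.01 + 2/mu` — bulk RNA-seq-like
  biological CV of ~10% at high counts plus shot noise at low counts.
- Library factors `L_s ~ U(0.7, 1.3)` — exercises size-factor estimation
  without extreme imbalance.
- 10% of genes DE at |log2fc| = 1 with random signs; a 179-member planted
  set whose members are DE with `set_de_enrichment x` baseline probability
  (error if `enrichment * frac_de > 1`).
- Drug-contrast effects are `-beta` for a `reversal_fraction` of the
  genotype-DE genes and `+beta` for the rest, so the planted fraction is
  the expected sign-flip rate among genes significant in both contrasts.
- Batch is a single binary latent covariate, assigned alternately within
  each design cell (orthogonal to the design by construction) with
  per-gene loadings `N(0, batch_sd)`; off by default.
- Phenotype: `c0 + c1 * (mean program-gene log2 CPM) + N(0, noise_sd)`,
  emulating Alizarin-red absorbance driven by an osteogenic program.
- Two optional program-structure switches, both off by default so the
  default model is exactly the equation above: `program_activity_sd` adds
  a shared per-sample latent "differentiation activity" loading on the
  program genes (sample-to-sample differentiation efficiency — the
  mechanism by which individual program genes, and not just the design
  axis, correlate with the phenotype); `program_coherent` makes DE
  program genes uniformly upregulated in HET, giving the program a common
  direction along the genotype axis as an osteogenic program has in the
  real tissue.

One master seed; counts, phenotype, and annotation draw from separate
child streams (`default_rng([seed, k])`), so components can be
regenerated independently. All outputs are pure functions of the
parameters including the seed.

The annotation generator places each gene's TSS in its own slot wide
enough that promoters and decoy clusters can never collide across genes;
target genes receive a cluster guaranteed ≥1 base of promoter overlap and
decoys are placed > flank away from every promoter, so the planted target
set is recovered exactly by construction.

**What the generator does not emulate:** gene–gene correlation beyond the
planted set/batch/program structure, GC/length bias, outlier samples and
count outliers, asymmetric up/down regulation, and a time trajectory of
differentiation (more DE at later time points is expressed simply as a
larger `frac_de`). Passing tests therefore validate the estimators under
a clean NB world; on real data, dispersion outliers and confounded batch
structure can degrade calibration in ways these tests do not measure.

## Problem sizes in the test suite

Simulation-based tests use 500–5,000 genes, 6 samples per group, and
100–500 Monte-Carlo repetitions with B = 1,000 permutation draws; the
full-resolution default (B = 10,000) is exercised once in the moment
checks of the permutation null. These sizes give the calibration
assertions Monte-Carlo error well inside their tolerance bands.

## Known limitations

- Wald inference with moment-based, trend-shrunk dispersions is slightly
  anticonservative at n = 12; likelihood-ratio tests and Cox–Reid
  dispersion estimation are out of scope.
- No independent filtering, outlier replacement, or LFC shrinkage.
- Median-of-ratios normalization assumes most genes are not differential.
- The surrogate estimator is single-pass residual PCA, not an iterated
  surrogate-variable algorithm.
- The permutation null draws subsets from tested (expression-filtered)
  genes; drawing from the pre-filter universe would give a slightly
  different null.
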