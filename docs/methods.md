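# Methods

## The gene-based test

The gene statistic is the sum of upper-tail χ²(1 df) transforms of the member
SNPs' p-values. If the members were in linkage equilibrium the null would be
χ²(n); LD makes the summands dependent, so the null is instead simulated:
z ~ MVN(0, Σ) with Σ the signed Pearson correlation matrix of the members'
reference-panel dosages, and each replicate contributes Σᵢzᵢ². This is exact
when the per-SNP statistics arise as squared z-scores whose correlation
matches the dosage correlation — which is the regime the synthetic generator
reproduces, making calibration checks sharp rather than approximate.

Assumptions worth keeping in mind:

* The panel stands in for the LD of the population the summary statistics
  came from; a mismatched panel biases Σ and hence the gene p.
* The two-sided-to-χ² conversion discards the direction of effect; only
  association strength is aggregated.
* SNP membership uses the "0 kb + LD" rule: inclusive boundaries plus
  recruitment of outside SNPs with r² > 0.8 against a within-boundary
  member. Linking is evaluated against boundary members only, not
  transitively — a config choice exposed as `r2_link`.

### Empirical p and the adaptive schedule

P = (r + 1)/(m + 1), with ties counting as "not surpassed" (a literal
reading of exceedance). Simulation escalates through stages of 10³, 10⁴,
10⁵, 10⁶ replicates, stopping at the first stage with ≥ 10 exceedances; each
stage draws fresh replicates from the gene's own RNG stream. Ten exceedances
keep the coefficient of variation of the estimate near 1/√10 ≈ 0.3
regardless of the p-value's magnitude, and the cap bounds runtime. Per-gene
streams are seeded from (global seed, blake2 hash of the gene symbol), so
results are reproducible, independent of gene iteration order, and stable
under parallel execution.

### Numerical choices

* **PSD repair**: finite panels routinely yield numerically indefinite Σ
  (more SNPs than individuals guarantees it). Eigenvalues are clipped at
  1e-8 and the diagonal renormalised to 1; a further 1e-8 ridge is added
  before the Cholesky factorisation. The repair perturbs a valid correlation
  matrix by at most ~1e-8 per entry.
* **p = 0 inputs** are clamped at ingest to 1e-300 (the χ² quantile diverges
  as p → 0); p = 1 maps to a zero summand.
* **Monomorphic SNPs** have undefined correlation and are dropped before Σ
  is built; missing dosages are mean-imputed per SNP. A gene whose members
  are all monomorphic is reported untested rather than erroring.
* **Top SNP** ties on p-value break by genomic position, making the report
  deterministic.

## Fisher meta-analysis and the threshold layers

x² = −2 Σ ln Pᵢ is referred to χ² with 2k df; for k = 1 this reduces to the
identity, which the tests exploit as a closed form. Fisher's method assumes
the per-trait p-values are independent — reasonable for non-overlapping
cohorts of the two traits. Every threshold in the pipeline is a strict
inequality. The cross-trait layer divides by 2n (n = overlap size, factor 2
for the two traits), exposed as `bonferroni_factor`; the expression layer
divides by the candidate-gene count G alone.

## Differential expression

The default statistic is the pooled-variance two-sample t on log2
expression — the unmoderated core of the linear-model workflow used by
GEO2R — with logFC = mean(case) − mean(control). Welch's t and a moderated t
are options. The moderated t implements standard empirical-Bayes variance
shrinkage: per-gene sample variances are treated as scaled-F draws around a
prior (d₀, s₀²) estimated by moment-matching on the log scale (digamma/
trigamma moments, trigamma inverted by Newton iteration), and each gene's
variance is squeezed to (d₀s₀² + df·s²)/(d₀ + df) with d₀ extra degrees of
freedom. The implementation is cross-checked against Bioconductor limma's
`eBayes` in the test suite.

Missing values are handled complete-case within each group; a group left
with fewer than two usable samples makes the gene NA for that study, and NAs
are ignored in the per-disease minima. Expression is assumed already
log2-normalised; no background correction, probe collapsing, or covariate
adjustment is performed. Repeated measures within a study are treated as
independent samples.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical* structure the pipeline consumes,
not human genomes:

* **Panel**: per-gene blocks of SNPs with AR(1) latent correlation
  `ld_rho` (adjacent-SNP copula correlation), thresholded into haplotypes at
  allele frequencies drawn U(0.05, 0.5) and summed to diploid dosages. Blocks
  are independent; there is no recombination map, population structure,
  realistic MAF spectrum, or long-range LD (hence nothing MHC-like).
* **GWAS**: z-scores drawn per block from MVN(λ, Σ_block) with Σ_block the
  panel's own dosage correlation; p = two-sided normal tail. λ = 0 for null
  SNPs, a configured noncentrality for causal ones. Because the gene test
  estimates Σ from the same panel, type-I calibration is exact by
  construction — passing calibration tests therefore validates the test's
  machinery, not its robustness to panel mismatch on real data.
* **Expression**: gene baselines N(8, 1) on the log2 scale with N(0, σ²)
  noise and additive planted logFC in cases; no probe effects, batch
  structure, or correlation between genes.

Defaults (chosen once as a realistic desk-scale regime): panel of 400
individuals, 2-12 SNPs per gene, `ld_rho` 0.6 — adjacent-dosage correlation
around 0.5, typical of within-gene LD; study designs default to σ = 0.5 on
the log2 scale with 10-15 samples per arm, matching small public case-control
series.

The end-to-end recovery scenario runs 200 genes with 5 shared-causal genes at
per-SNP λ = 4 for 20 replicates, with the simulation cap at 10⁴ replicates
per gene; the resulting empirical-p floor of 1e-4 sits two orders of
magnitude below the layered threshold in that scenario, so the cap does not
constrain the screen. Larger caps (up to the default 10⁶) only sharpen
p-values beyond what the decision needs.

## Known limitations

* The LD-recruitment rule links outside SNPs only to boundary members; a
  transitive closure could recruit slightly more SNPs.
* Empirical p-values are bounded below by 1/(m+1); genes at the floor are
  reported at the floor, not extrapolated.
* Fisher's method presumes cross-trait independence; shared controls between
  cohorts would inflate the combined significance.
* The expression stage reports raw per-study p-values and applies the
  layered Bonferroni rule; no FDR alternative is wired into the headline
  path (`classify_shared` accepts any threshold inputs if one is needed).
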