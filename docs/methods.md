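# Methods

`extgen` partitions plant-trait variance into genetic and DNA-methylation
components in clonal populations, where the two sources are strongly
confounded: accessions that are nearly genetically identical also share most
of their methylome. The package fits both jointly so that the methylation
component is estimated *given* the genetic relatedness, not instead of it.

## Population structure and data model

The target design is a nested clonal hierarchy: a small number of clone
families (groups of accessions that are nearly genetically identical), each
containing several accessions, each grown in biological replicates in a
common environment. Three data layers enter the analysis:

1. **SNP genotypes** for one representative accession per clone family,
   coded 0/1 (homozygous reference / homozygous alternate). Highly selfing
   species are effectively fully homozygous, so heterozygous codes are
   rejected at input.
2. **Whole-genome bisulfite call sets** per plant (per-cytosine methylated /
   unmethylated read counts), CG context only. Non-CG contexts occur at
   lower levels and are poorly measured at low coverage, so they are
   excluded from the similarity model.
3. **Plant-level trait values** with the plant → accession → clone-family
   maps and an environment label; environments are analysed separately.

## Genomic relatedness (G)

SNPs are filtered to those with at least one copy of the minor allele and at
most one missing call across families. Genotypes are centered by the sample
allele frequency, W_ij = x_ij − p_j (missing cells set to 0, i.e. mean
imputation), and

    G = W W' / Σ_j p_j (1 − p_j).

Under 0/1 coding the variance of a genotype is p(1−p), so this denominator —
half the diploid-dosage convention — is what makes the matrix scale
correctly for homozygous lines: for frequency-matched random genotypes the
mean diagonal tends to 1 as the SNP count grows. With sample-frequency
centering of n families the expected mean diagonal is (n−1)/n; see
"Variance fractions" below for how this is handled when converting fitted
components to fractions.

G from cross-products is PSD but typically singular (families ≪ SNPs, and
centering puts the ones-vector in the null space). The fitting engine never
inverts G; eigenvalue bending (floor 10⁻⁶ × mean positive eigenvalue) is
applied only where a valid covariance is required for sampling or when a
structure is indefinite.

## Methylation similarity (M)

Replicate call sets are pooled per accession (read counts added per site).
CG sites are binned into non-overlapping 200 bp windows anchored at
coordinate 0 (0-based half-open; input positions are 1-based per the usual
cytosine-report convention). A window's level for an accession is the
pooled-count ratio Σmeth/Σtotal, treated as missing below 10 reads. Windows
missing in more than 50% of accessions (strictly more — exactly half is
kept) or containing no methylated read at all are dropped; the two rules
are independent predicates, so their order is immaterial.

Window columns of the resulting proportion matrix Q are standardized to
mean 0 and unit variance over their observed entries. We use the population
variance (divide by the count, not count−1) so that with complete data
trace(M)/n = 1 exactly. Missing cells then contribute 0 to the
cross-product, giving the pairwise-complete estimator

    M = Q Q' / N,     N_ij = number of windows observed in both i and j.

Pairwise-complete estimation can leave M slightly indefinite; it is
eigenvalue-bent (same floor) before use as a covariance, with the
`psd_adjusted` flag set. Strand is kept as reported (no symmetric-CpG
merging): once sites are pooled into 200 bp windows the distinction is
immaterial for the matrix.

## Variance partitioning

For each trait and environment, two nested mixed models are fitted by REML:

    reduced:  y = 1μ + Z_g v + ε,          v ~ N(0, σ²_g G)
    full:     y = 1μ + Z_g v + Z_m ρ + ε,  ρ ~ N(0, σ²_m M)

with Z_g and Z_m the plant → clone-family and plant → accession incidence
matrices. The marginal covariance V = σ²_g Z_g G Z_g' + σ²_m Z_m M Z_m' +
σ²_e I is used directly; no inversion of G or M is needed. Plants with a
missing value for the analysed trait are dropped for that trait's fit only.

**Optimizer.** The restricted likelihood (intercept-only fixed effects) is
maximized over log-variances with L-BFGS-B using the exact analytic REML
gradient, ∂ℓ/∂σ²_k = −½[tr(P K_k) − y'P K_k P y], plus a Nelder–Mead polish
if the gradient-based search reports failure. The log parameterization
enforces non-negativity with a hard floor at 10⁻¹⁰ × Var(y); estimates
below 10⁻⁶ × Var(y) are flagged as boundary. Convergence tolerance is
10⁻¹³ on the (unit-scaled) objective, at most 200 iterations; y is
standardized internally for conditioning and estimates mapped back. On
balanced one-way designs with G = I the estimates agree with the
ANOVA closed form to ~10⁻⁹ relative, and on small problems the optimum
matches dense grid search of an independently coded restricted likelihood.
A constant trait yields a flagged degenerate result (all components zero)
rather than an error.

**Testing the methylation component.** The statistic 2(ℓ_full − ℓ_reduced),
clipped at zero, is referred to χ² with one degree of freedom. REML
log-likelihoods are comparable because both models share the same fixed
effects. The true null distribution at the σ²_m = 0 boundary is the mixture
½χ²₀ + ½χ²₁, so the plain χ²(1) reference is conservative; the null
calibration run (500 simulated null data sets at n = 252) confirms an
empirical type-I rate below the nominal 0.05.

**Reporting.** Components are mean-standardized (Houle's I = σ²/ȳ²,
printed ×100, with ȳ the mean of the plants entering that fit) and
converted to variance fractions H²_SNP = σ²_g/(σ²_g+σ²_m+σ²_e), H²_CG
analogously — the plain ratios that reproduce a published-style components
table. Group-level BLUPs are available (`blup`) but unused in the headline
report.

**Variance fractions as estimands.** Plain component ratios are unbiased
fractions only when each structure has unit mean diagonal.
`VariancePartition.fractions()` therefore weights each σ̂² by
tr(Z K Z')/n recorded at fit time; this is the quantity the simulation
recovery checks use, and it is consistent with how the generator scales
effect variances (below). For structures with mean diagonal ≈ 1 — M by
construction, G up to the (n−1)/n factor — the two summaries differ by a
few percent at most.

## Simplified pairwise DMR caller

The caller is a transparent stand-in for histogram-feature/SVM pairwise DMR
tools, built from the three ingredients those tools describe: per shared CG
site a coverage-weighted two-group comparison (the pooled two-proportion
score test, identical to the score test of a binomial logistic regression
on the group indicator with read-count weights); moving-average smoothing of
the per-site differences over ±2 sites weighted by (1 − p) so uncertain
sites contribute less; and segmentation of maximal same-sign runs of
smoothed |Δ| ≥ 0.2, kept when spanning ≥ 4 CGs and ≥ 50 bp, with the
reported Δ the coverage-weighted mean raw difference (also required to
clear the threshold). Sites present in only one sample are skipped. Calls
are symmetric under swapping the samples (deltas negate), and raising any
threshold can only reduce the call count.

For nested summaries, replicate-level comparisons pair individual plants of
an accession; within- and between-family comparisons pair replicate-pooled
accessions (all pairs; a random subset may be drawn for large populations).
Absolute counts depend on coverage and thresholds and are not comparable
across studies; the robust, design-driven signal is the ordering
inter-family > intra-family > replicate.

## Synthetic populations

The generator produces the full data triple with known architecture.

* **Genotypes**: per-SNP alternate-allele frequency ~ Uniform(0.1, 0.9);
  each family draws one homozygous genotype shared by all its accessions;
  one representative row per family forms the SNP matrix. Default 300 SNPs.
* **Methylomes**: window logit-level = baseline (sd 1.0) + family effect
  (sd 1.2) + accession effect (sd 0.4) + per-plant replicate effect
  (sd 0.2); all CG sites of a window share its level, site coverage is
  Poisson (default mean 3, the low-coverage regime; 10–30 for
  high-coverage runs) and methylated counts binomial. The layer ordering
  (family ≫ accession > replicate) makes methylation similarity track the
  family structure, which is exactly the confounding the joint model
  exists to handle. Effects on the logit scale keep proportions in (0,1);
  the single-Gaussian baseline does not reproduce the bimodal
  (TE-high/genic-low) landscape of real plant methylomes, nor positional
  autocorrelation within windows, so passing tests speak to the estimator
  contracts, not to every property of real data.
* **Phenotypes**: y = mean + Z_g v + Z_m ρ + ε with v and ρ drawn against
  the bent G and the M *computed from the simulated methylomes*. Component
  variances are scaled by the mean diagonal of the induced covariance so
  the population variance fractions equal the requested (h²_g, h²_m).

Defaults (7 × 12 × 3 = 252 plants, 120 windows of 5 CGs) keep a full
dataset ~1 s and a REML fit ~0.1 s, which is what makes the 500-replicate
null calibration and 20-seed recovery studies routine. Null-calibration
runs redraw the phenotype vector against one fixed genotype/methylome
background, since the LRT null concerns the trait model only.

## Known limitations

* Environments are modelled separately; no G×E or multi-trait models, and
  no dominance/epistatic terms — the clone-family design cannot separate
  them from the family effect.
* The similarity matrix treats windows as exchangeable; no weighting by
  window informativeness or local sequence context.
* The DMR caller does not control genome-wide FDR and is not a
  reimplementation of any published classifier; its absolute counts should
  not be compared against published tables.
* With very few families (the realistic regime) σ̂²_g has large sampling
  variance; single-dataset fractions are noisy even when the average over
  seeds is accurate.
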