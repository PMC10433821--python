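# Methods

This note records the models, defaults and numerical choices behind
`cnvmicro`, and what the synthetic cohorts do and do not emulate.

## Synthetic cohorts

The generator (`cnvmicro.simulate`) produces every matrix the analysis
consumes, on one shared sample axis, from a single seed (each component
draws from an independent, seed-derived stream, so any matrix is
reproducible in isolation).

* **SNP genotypes.** Allele frequencies p ~ Uniform(maf_range)
  (default 0.05–0.5), dosages Binomial(2, p) per individual: a panmictic
  Hardy–Weinberg cohort with no linkage, no relatedness structure beyond
  sampling noise, and no association between SNPs and the planted CNV.
* **Binned depth.** Poisson(mean_depth · c/2) per 20-kb bin, where c is
  the sample's true copy number (2 outside CNVs).  Default mean_depth is
  100 reads/bin; an optional negative-binomial dispersion models
  overdispersed coverage but is off by default, as ratio-based calling is
  exercised adequately by the Poisson.
* **Planted CNVs.** Each CNV has an interval, type (gain/loss), carrier
  fraction and carrier copy number in {0, 1, 3, 4}; carriers are a
  uniform random subset.  The default study plants one 80-kb gain
  (copy number 3) carried by 25% of 100 individuals — sized after a
  single-farm pig cohort with a segregating duplication.
* **Microbiome.** The CNV→diversity link is modelled as taxon-pool
  occupancy, not abundance shifts: non-carriers draw their community
  from a random pool of `base_pool` ASVs (default 600 of 1,000),
  carriers from `base_pool + round(diversity_effect · dup_pool_bonus)`
  (default +100).  Within-pool relative abundances are symmetric
  Dirichlet (concentration 1) and counts Multinomial at 20,000
  reads/sample.  This directly induces the target phenotype — higher
  richness and Shannon diversity in carriers — without asserting which
  taxa respond.  `diversity_effect = 0` switches the link off for null
  calibration.  Defaults were chosen so non-carrier richness sits near
  600 ASVs with a carrier excess near 100, the scale reported for pig
  fecal communities at 10,000-read rarefaction.
* **Covariates.** Sex (M/F) and batch (3 levels) round-robin; an
  optional additive batch offset on pool size exercises the fixed
  effects.
* **qPCR.** Target-assay Ct = ct_base − log2(c/2)/log2(1+E) + noise
  (E = amplification efficiency, default 1.0 = perfect doubling;
  noise SD 0.15 cycles), control-assay Ct = ct_base + noise,
  four replicate wells per assay.

What the cohorts do **not** emulate: GC or mappability bias, linkage
disequilibrium and kinship, read-level errors, compositional
interactions between taxa, or any coupling between the SNP haplotype
background and CNV carrier status.  Consequently a passing suite shows
the estimators and tests behave as specified under their stated
assumptions — not that the pipeline is robust to real-data artifacts;
and the correlation between qPCR relative quantity and the nucleotide-
diversity estimators is null in synthetic data by construction.

## CNV discovery

Depth is normalised by the pooled per-bin median (≥3 samples required),
then rescaled so each sample's median ratio is 1; zero-baseline bins are
masked and never called.  Thresholds 1.25/0.75 with a 2-bin minimum are
the midpoints between diploid (ratio 1) and a single-copy change
(1.5/0.5), guarding against single-bin noise; same-sample, same-status
calls < 10 kb apart are merged across the gap.

CNVR clustering uses ≥ 50% reciprocal overlap, evaluated between
cluster union extents.  Pairwise merging to a fixpoint is **order
dependent** (merging changes extents, which changes later predicates),
so the merge order is part of the definition: repeatedly merge the
first pair of cluster extents in (chrom, start, end) order whose
reciprocal overlap is ≥ 0.5, until no pair qualifies.  The production
sweep exploits coordinate sorting for early termination; the test suite
holds it to partition equality with a naive full-rescan implementation
of the same rule on random instances.

Genotyping: a sample's status at a CNVR is its member call's status
(diploid if none); a sample with both gain and loss overlap inside one
region takes the status with the larger overlapped length, with exact
ties logged and set diploid.  "At least 5% of samples" is read
inclusively (frequency ≥ 0.05 kept).  Coordinates are BED-style 0-based
half-open everywhere.

## Diversity

Samples are rarefied to exactly 10,000 reads by multivariate-
hypergeometric subsampling (true sampling without replacement);
shallower samples are dropped with a warning.  Richness is the positive-
count ASV number; Shannon uses natural log by default (configurable to
base 2) — group means near 6 at richness ~600 are only consistent with
the natural-log convention.  Whittaker β for a pair is
S_union/mean(S_A, S_B) − 1; the per-group statistic is the mean over
within-group pairs, the standard multi-sample extension when a single
per-group value is wanted.  Group comparisons use Welch's t-test, with
a permutation p-value available; a degenerate comparison (both groups
constant and equal) reports p = 1.

## Mixed-model association

The GRM is VanRaden method 1, G = WWᵀ/(2Σpₖ(1−pₖ)) on column-centred
dosages, monomorphic SNPs excluded.  The null model (no CNV term) is
fitted by REML in the eigenbasis of G: for each variance ratio
λ = σ²ᵤ/σ²ₑ the residual scale and fixed effects are profiled in closed
form; λ is bracketed on a 49-point log grid spanning 10⁻⁶–10⁶ and
refined by bounded Brent search, with the λ = 0 boundary always
compared against the interior optimum.  Eigenvalues are clipped at
zero; a matrix still indefinite after a 1e−8 jitter is an error, as is
a rank-deficient fixed-effect design (the collinear columns are named).

Each CNVR dosage (loss/diploid/gain → 0/1/2, the additive re-expression
of a 11/12/22 coding) is tested by GLS with V = σ̂²ᵤG + σ̂²ₑI held fixed
from the null — the MLMA convention, O(n) per marker after the
eigendecomposition — with a two-sided Wald χ²₁ p-value.  A second mode
(`scale="refit"`) keeps only the ratio fixed, re-profiles the residual
scale with the marker included and uses a Student-t reference; with
σ²ᵤ = 0 it reduces exactly to the OLS t-test, which the suite checks to
1e−8.  FDR is Benjamini–Hochberg, applied per trait (richness and
Shannon corrected separately).  Constant dosages are skipped with a
recorded reason.

## Per-individual nucleotide diversity

For individual j, ξᵢ counts segregating sites at population alternate-
allele count i (unfolded by default; a folded option exists) carried
with dosage ≥ 1 — heterozygous and homozygous-alternate sites each
count once.  The simple estimator is Σξᵢ/L.  The corrected estimator is

θ̂ = C(n,2)⁻¹ Σᵢ i(n−i) ξᵢ [1 − C(n−i,2)/C(n,2)]⁻¹ / L

with C(m,2) = 0 for m < 2.  Because the normaliser Σᵢ(n−i) equals
C(n,2), the uncorrected part is exactly Tajima's π restricted to the
carried sites, and the bracketed factor is the reciprocal of the
hypergeometric probability that a diploid individual carries an allele
segregating at count i; the flattened one-line form of this expression
is ambiguous between an i·(n−i) product and an (n−i)/i ratio in the
summand, and the product reading is adopted because it is the one under
which the estimator's mean over individuals is unbiased for population
π — the property the suite verifies on neutral cohorts (median relative
error < 5% at 100 individuals × 2,000 sites).  The effective length L
is supplied by the caller (region length for simulations, callable
sites for real data), never inferred.

## qPCR quantification

ΔCt = mean target Ct − mean control Ct per sample; ΔΔCt references the
mean ΔCt of designated diploid samples (three by default); RQ = 2^−ΔΔCt.
Perfect doubling is assumed in the transform, matching the plain
2^−ΔΔCt method; the simulator can generate lower efficiencies to probe
the resulting bias.  Replicate wells more than 0.5 cycles from their
sample-assay median are dropped (plate QC is otherwise unspecified);
samples left with fewer than two usable replicates, or missing an
assay, are skipped and logged.  Status thresholds RQ ≥ 1.25 → DUP and
RQ ≤ 0.75 → LOSS mirror the depth-ratio thresholds.  Concordance
precision is the percentage of samples whose qPCR status equals the
in-silico status, to two decimals; Pearson correlation links RQ to
diversity and to the per-individual estimators.

## Microbial signatures

Counts receive a pseudocount of 1 (the zero-replacement rule is
otherwise unspecified) and the CLR transform; the linear kernel on CLR
coordinates is the Aitchison inner product, so the "compositional
kernel" classifier is realised as a soft-margin linear SVM (libsvm
hinge-loss) with an explicit primal weight vector, making the (wₖ)²
importance well defined.  Ten stratified 80/20 splits; cost C tuned per
split over {0.01, 0.1, 1, 10, 100} by 10-repeat 10-fold stratified CV,
ties resolved toward the smaller C (stronger regularisation); top 5%
of features by (wₖ)² per replicate; consensus = features selected in at
least half the replicates.  Genus enrichment of the consensus uses the
hypergeometric upper tail with BH correction across genera.
Differential abundance aggregates counts to genus, converts to relative
abundance and applies two-sided Wilcoxon rank-sum with BH correction
and star bands — a deliberate surrogate for the unspecified test, so
specific genus lists are not comparable across implementations.

## Problem sizes and determinism

Statistical suite sizes are chosen to make the checks sharp at desk
scale: estimator unbiasedness over 20 seeds of 100×2,000 cohorts;
mixed-model type-I error over 1,000 null tests at n = 300 and power
over 20 seeds (trait = sex + batch + polygenic(h² = 0.5) + residual at
unit SD, 0.5-SD carrier effect at frequency 0.25); clustering-oracle
equality over 200 random 20-interval instances; signature recovery at
20 planted features among 500 over 100 samples; end-to-end behaviour
over 20 seeds each for the planted-effect cohort (one linked gain plus
five neutral decoys) and the null cohort (50 neutral CNVRs).  All
randomness flows through explicit seeds; a fixed seed reproduces every
matrix, report and p-value bit-for-bit.

## Known limitations

Single-trait, single-focal-CNVR follow-up; no GC/mappability
correction, B-allele frequencies or breakpoint refinement; no
phylogenetic diversity or ordination; no SNP GWAS; heritability is
reported without a standard error; the Wald test at fixed variance
components is slightly anticonservative at small n, which the
calibration suite bounds at n = 300.
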