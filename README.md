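# cnvmicro

Do structural variants in a host genome modulate the diversity of its gut
microbiota?  `cnvmicro` is an end-to-end toolkit for asking that question
the way it is asked in livestock genomics: discover copy-number variants
(CNVs) from binned whole-genome read depth, collapse them into
copy-number variant regions (CNVRs), and test each region against
16S-derived microbial diversity with a genomic-relationship mixed model —
then validate the focal region with qPCR relative quantification,
per-individual nucleotide-diversity estimators and a compositional-kernel
SVM signature of the community shift.

It is aimed at researchers analysing cohorts with matched host WGS (or
binned coverage), SNP genotypes and 16S ASV tables — and it ships a
synthetic-cohort generator that plants a diversity-modulating CNV, so
every stage is testable without any real data.

## The analysis

**CNV discovery.** Per-sample binned depth (20-kb bins by default) is
normalised by the pooled per-bin median, thresholded (gain ≥ 1.25,
loss ≤ 0.75, ≥ 2 bins), and same-status calls < 10 kb apart are merged.
Calls are clustered into CNVRs by ≥ 50% reciprocal overlap of cluster
extents; samples are genotyped loss/diploid/gain (dosage 0/1/2) and
regions carried by < 5% of samples are dropped.

**Association.** For a diversity trait *y* (rarefied richness or Shannon
index), the model is

y = sex + batch + u + β·cnv + e,  u ~ N(0, G σ²ᵤ)

with G the VanRaden genomic relationship matrix from autosomal SNPs.
Variance components are REML-estimated once under the null (eigendecomposition
of G, one-dimensional search over σ²ᵤ/σ²ₑ); each CNVR dosage then gets a
Wald test at the fixed null covariance, and Benjamini–Hochberg FDR is
applied per trait.

**Per-individual nucleotide diversity.** For individual *j* with
carried-site frequency spectrum ξᵢ (sites at population alternate count
*i* that *j* carries) over *n* chromosomes:

θ̂ = C(n,2)⁻¹ Σᵢ i(n−i) ξᵢ [1 − C(n−i,2)/C(n,2)]⁻¹ / L

The bracketed factor inverts the hypergeometric probability that a
diploid carries an allele at count *i*, making the mean of θ̂ over
individuals an unbiased estimate of population π.  The uncorrected count
of carried variants per nucleotide is reported alongside.

**Validation and signatures.** qPCR Ct plates are reduced by 2^−ΔΔCt
against diploid reference samples, classified 2N/DUP/LOSS, and scored
for concordance with the in-silico genotypes.  ASV counts are CLR-
transformed (the linear kernel on CLR equals the Aitchison inner
product) and a soft-margin linear SVM over ten stratified 80/20 splits,
with the cost tuned by 10×10 cross-validation, yields (wₖ)² feature
importances; the top 5% per replicate and a ≥ 50%-replicate consensus
define the microbial signature, followed by hypergeometric genus
enrichment and Wilcoxon differential abundance.

## Worked example

```
cnvmicro pipeline --out run1 --seed 4 --no-signatures
```

prints (seed 4, default synthetic cohort of 100 individuals with one
planted 80-kb gain at 25% carrier frequency):

```
  CNV calls: 25  CNVRs: 1  after 5% filter: 1
  richness: top CNVR1  beta=84.9  p=4.48e-22  q=4.48e-22  (h2=0.20, 1 significant)
  shannon: top CNVR1  beta=0.132  p=2.98e-19  q=2.98e-19  (h2=0.00, 1 significant)
  qPCR concordance: 100.00%
  RQ ~ richness: r=0.931 p=1.28e-44
  RQ ~ shannon: r=0.869 p=1.23e-31
  RQ ~ rtajima: r=-0.052 p=0.611
  Whittaker beta by group: 2N=0.433, DUP=0.347
```

Reading: the planted gain is recovered as the single CNVR surviving the
5% carrier filter; its dosage raises rarefied richness by ≈ 85 ASVs per
copy (Wald p ≈ 4×10⁻²²); qPCR relative quantification agrees with every
in-silico genotype and correlates strongly with diversity; and carriers
show *lower* within-group Whittaker β (0.347 vs 0.433) — a more
homogeneous community, as expected when carriers draw from a shared,
larger taxon pool.  The RQ ~ RTajima correlation is null by design: the
generator does not couple SNP haplotypes to the CNV.

Every stage is also a library call (`simulate_cohort`, `normalize_depth`
→ `call_segments` → `build_cnvrs` → `genotype_cnvrs`, `diversity_table`,
`CnvAssociation(...).fit()`, `delta_delta_ct`, `popgen_table`,
`SignatureClassifier(...).fit()`) and a CLI subcommand (`simulate`,
`cnv`, `diversity`, `assoc`, `popgen`, `qpcr`, `signatures`,
`pipeline`); intermediate artifacts are plain TSV/BED/VCF so any stage
can be re-run in isolation.

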