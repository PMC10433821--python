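"""Synthetic cohort generator.

Emulates the data a CNV-microbiome association study consumes: a SNP
genotype matrix in Hardy-Weinberg proportions, binned whole-genome read
depth with planted multi-sample CNVs, a fecal ASV count table whose
richness depends on CNV carrier status, sample covariates (sex, batch)
and a qPCR Ct plate consistent with the true copy numbers.

The CNV -> microbiome link is modelled through taxon-pool occupancy:
carriers of the planted gain sample their community from a larger pool
of accessible taxa, which directly raises expected richness and Shannon
diversity without dictating the abundance distribution.  All randomness
flows from ``SimConfig.seed`` through independent per-component streams,
so each piece of the cohort is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PlantedCnv",
    "SimConfig",
    "SimulatedCohort",
    "simulate_genotypes",
    "simulate_coverage",
    "simulate_microbiome",
    "simulate_qpcr",
    "simulate_covariates",
    "simulate_cohort",
]

#: genus labels used for the synthetic taxonomy; common swine gut genera
GENUS_POOL = [
    "Prevotella", "Lactobacillus", "Clostridium", "Ruminococcus",
    "Faecalibacterium", "Blautia", "Roseburia", "Desulfovibrio",
    "Phascolarctobacterium", "Fibrobacter", "Megasphaera", "Succinivibrio",
    "Coprococcus", "Anaerovibrio", "Bacteroides", "Oscillospira",
    "Treponema", "Streptococcus", "Dialister", "Butyrivibrio",
    "Parabacteroides", "Akkermansia", "Bifidobacterium", "Dorea",
    "Eubacterium", "Mitsuokella", "Sarcina", "Selenomonas",
    "Sphaerochaeta", "Turicibacter",
]

# sub-stream tags so each component has an independent, reproducible RNG
_STREAM_GENO = 1
_STREAM_DEPTH = 2
_STREAM_MICROBIOME = 3
_STREAM_QPCR = 4


class ConfigError(ValueError):
    """Raised when a simulation configuration violates an invariant."""


@dataclass(frozen=True)
class PlantedCnv:
    """A copy-number variant planted into the simulated genome.

    ``copy_number`` is the carrier's total copy count (diploid = 2), so
    gains use 3 or 4 and losses 0 or 1.
    """

    chrom: str
    start: int
    end: int
    kind: str  # "gain" | "loss"
    carrier_fraction: float
    copy_number: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConfigError(f"CNV end must exceed start: {self}")
        if self.kind not in ("gain", "loss"):
            raise ConfigError(f"CNV kind must be gain or loss: {self.kind!r}")
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ConfigError("carrier_fraction must lie in [0, 1]")
        if self.copy_number not in (0, 1, 3, 4):
            raise ConfigError("copy_number must be one of {0, 1, 3, 4}")
        if self.kind == "gain" and self.copy_number < 3:
            raise ConfigError("gain requires copy_number >= 3")
        if self.kind == "loss" and self.copy_number > 1:
            raise ConfigError("loss requires copy_number <= 1")


def _default_cnvs() -> list[PlantedCnv]:
    return [PlantedCnv("1", 1_000_000, 1_080_000, "gain", 0.25, 3)]


@dataclass
class SimConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror a single-farm pig cohort of 100 animals (balanced
    sexes, three batches), 20-kb depth bins with one planted 80-kb gain
    carried by a quarter of the animals, and a gut community whose
    non-carrier samples draw ~600 of 1,000 ASVs.
    """

    n_individuals: int = 100
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    genome_length: int = 2_000_000
    bin_size: int = 20_000
    planted_cnvs: list[PlantedCnv] = field(default_factory=_default_cnvs)
    mean_depth: float = 100.0
    depth_overdispersion: float | None = None  # NB dispersion; None = Poisson
    n_taxa: int = 1000
    base_pool: int = 600
    dup_pool_bonus: int = 100
    library_size: int = 20_000
    dirichlet_concentration: float = 1.0
    diversity_effect: float = 1.0
    batch_diversity_offset: float = 0.0
    ct_base: float = 22.0
    ct_noise_sd: float = 0.15
    amplification_efficiency: float = 1.0
    n_batches: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_snps", "genome_length", "bin_size",
                     "n_taxa", "base_pool", "library_size", "n_batches"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range bounds must satisfy 0 < lo <= hi <= 0.5")
        if self.genome_length % self.bin_size != 0:
            raise ConfigError("bin_size must divide genome_length")
        if self.base_pool + self.dup_pool_bonus > self.n_taxa:
            raise ConfigError("base_pool + dup_pool_bonus must not exceed n_taxa")
        if not (0.5 < self.amplification_efficiency <= 1.0):
            raise ConfigError("amplification_efficiency must lie in (0.5, 1]")
        if self.dirichlet_concentration <= 0:
            raise ConfigError("dirichlet_concentration must be positive")
        for cnv in self.planted_cnvs:
            if cnv.start < 0 or cnv.end > self.genome_length:
                raise ConfigError(f"planted CNV outside the genome: {cnv}")
        # overlapping CNVs of conflicting type are ambiguous
        by_chrom: dict[str, list[PlantedCnv]] = {}
        for cnv in self.planted_cnvs:
            by_chrom.setdefault(cnv.chrom, []).append(cnv)
        for cnvs in by_chrom.values():
            cnvs = sorted(cnvs, key=lambda c: c.start)
            for a, b in zip(cnvs, cnvs[1:]):
                if b.start < a.end and a.kind != b.kind:
                    raise ConfigError(
                        f"overlapping planted CNVs of conflicting type: {a} / {b}")

    @property
    def n_bins(self) -> int:
        return self.genome_length // self.bin_size

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_individuals)]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class SimulatedCohort:
    """All matrices of a synthetic cohort, sharing one sample axis."""

    config: SimConfig
    genotypes: pd.DataFrame          # individuals x SNPs, dosage 0/1/2
    snp_positions: pd.DataFrame      # chrom, pos per SNP
    depth: pd.DataFrame              # samples x bins, integer read counts
    bins: pd.DataFrame               # chrom, start, end per bin
    asv_counts: pd.DataFrame         # samples x ASVs, integer counts
    taxonomy: pd.Series              # ASV id -> genus
    covariates: pd.DataFrame         # sex, batch per sample
    ct_table: pd.DataFrame           # sample, assay, replicate, ct
    truth: pd.DataFrame              # per sample: copy_number, carrier per CNV

    def __post_init__(self) -> None:
        idx = self.genotypes.index
        for name in ("depth", "asv_counts", "covariates", "truth"):
            other = getattr(self, name).index
            if not idx.equals(other):
                raise ConfigError(f"sample axis mismatch between genotypes and {name}")


def simulate_genotypes(config: SimConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a biallelic SNP dosage matrix under Hardy-Weinberg equilibrium.

    Each SNP gets an allele frequency p ~ Uniform(maf_range) and genotypes
    Binomial(2, p) independently per individual.
    """
    rng = rng or config.rng(_STREAM_GENO)
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=config.n_snps)
    dosages = rng.binomial(2, freqs, size=(config.n_individuals, config.n_snps))
    snp_ids = [f"snp{i + 1}" for i in range(config.n_snps)]
    return pd.DataFrame(dosages, index=config.sample_ids, columns=snp_ids)


def snp_positions(config: SimConfig) -> pd.DataFrame:
    """Evenly spaced SNP coordinates on the simulated chromosome."""
    pos = np.linspace(1, config.genome_length, config.n_snps, dtype=int)
    return pd.DataFrame({
        "chrom": "1",
        "pos": pos,
    }, index=[f"snp{i + 1}" for i in range(config.n_snps)])


def bin_table(config: SimConfig) -> pd.DataFrame:
    """0-based half-open bin coordinates covering the genome."""
    starts = np.arange(0, config.genome_length, config.bin_size)
    return pd.DataFrame({
        "chrom": "1",
        "start": starts,
        "end": starts + config.bin_size,
    }, index=[f"bin{i + 1}" for i in range(config.n_bins)])


def simulate_coverage(config: SimConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw the binned depth matrix and the carrier truth table.

    Bin depth is Poisson(mean_depth * c / 2) where c is the sample's true
    copy number in that bin (2 outside planted CNVs).  With
    ``depth_overdispersion`` set, a negative-binomial with that dispersion
    replaces the Poisson.  Carriers of each planted CNV are a random
    subset of round(carrier_fraction * n) samples.
    """
    rng = rng or config.rng(_STREAM_DEPTH)
    bins = bin_table(config)
    n, n_bins = config.n_individuals, config.n_bins
    copy = np.full((n, n_bins), 2, dtype=float)

    truth_cols: dict[str, np.ndarray] = {}
    for cnv in config.planted_cnvs:
        n_carriers = int(round(cnv.carrier_fraction * n))
        carriers = rng.choice(n, size=n_carriers, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[carriers] = True
        in_cnv = ((bins["chrom"] == cnv.chrom)
                  & (bins["start"] < cnv.end)
                  & (bins["end"] > cnv.start)).to_numpy()
        copy[np.ix_(mask, in_cnv)] = cnv.copy_number
        tag = f"{cnv.chrom}:{cnv.start}-{cnv.end}"
        truth_cols[f"carrier_{tag}"] = mask
        truth_cols[f"copies_{tag}"] = np.where(mask, cnv.copy_number, 2)

    lam = config.mean_depth * copy / 2.0
    if config.depth_overdispersion is None:
        depth = rng.poisson(lam)
    else:
        # NB parameterised by mean lam and dispersion k: var = lam + lam^2/k
        k = config.depth_overdispersion
        depth = rng.negative_binomial(k, k / (k + np.maximum(lam, 1e-12)))
        depth[lam == 0] = 0
    depth_df = pd.DataFrame(depth, index=config.sample_ids, columns=bins.index)
    truth = pd.DataFrame(truth_cols, index=config.sample_ids)
    return depth_df, bins, truth


def simulate_microbiome(config: SimConfig,
                        carrier_status: np.ndarray | pd.Series,
                        batches: np.ndarray | pd.Series | None = None,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Draw the ASV count table given per-sample CNV carrier status.

    Non-carriers draw their community from a random pool of ``base_pool``
    taxa; carriers from ``base_pool + round(diversity_effect *
    dup_pool_bonus)`` taxa.  Relative abundances within the pool follow a
    symmetric Dirichlet and counts a multinomial at ``library_size``.
    """
    rng = rng or config.rng(_STREAM_MICROBIOME)
    status = np.asarray(carrier_status, dtype=bool)
    if status.shape[0] != config.n_individuals:
        raise ConfigError("carrier_status length must equal n_individuals")
    bonus = int(round(config.diversity_effect * config.dup_pool_bonus))
    if config.base_pool + max(bonus, 0) > config.n_taxa:
        raise ConfigError("effective carrier pool exceeds n_taxa")
    batch_idx = np.zeros(config.n_individuals, dtype=int)
    if batches is not None:
        batch_idx = pd.factorize(np.asarray(batches))[0]

    counts = np.zeros((config.n_individuals, config.n_taxa), dtype=int)
    for s in range(config.n_individuals):
        pool_size = config.base_pool + (bonus if status[s] else 0)
        pool_size += int(round(config.batch_diversity_offset * batch_idx[s]))
        pool_size = int(np.clip(pool_size, 1, config.n_taxa))
        pool = rng.choice(config.n_taxa, size=pool_size, replace=False)
        props = rng.dirichlet(np.full(pool_size, config.dirichlet_concentration))
        counts[s, pool] = rng.multinomial(config.library_size, props)

    asv_ids = [f"ASV{i + 1:04d}" for i in range(config.n_taxa)]
    table = pd.DataFrame(counts, index=config.sample_ids, columns=asv_ids)
    genera = rng.choice(GENUS_POOL, size=config.n_taxa, replace=True)
    taxonomy = pd.Series(genera, index=asv_ids, name="genus")
    return table, taxonomy


def simulate_qpcr(config: SimConfig,
                  true_copies: np.ndarray | pd.Series,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a long-format Ct plate (quadruplicate wells per assay).

    The target assay shifts by -log2(copies/2)/log2(1+E) cycles relative
    to ``ct_base`` (E = amplification efficiency; E = 1 is perfect
    doubling); the single-copy control assay stays at ``ct_base``.
    """
    rng = rng or config.rng(_STREAM_QPCR)
    copies = np.asarray(true_copies, dtype=float)
    if np.any(copies < 1):
        raise ConfigError("true_copies must be >= 1 for the target assay")
    samples = config.sample_ids
    if copies.shape[0] != len(samples):
        raise ConfigError("true_copies length must equal n_individuals")

    shift = np.log2(copies / 2.0) / np.log2(1.0 + config.amplification_efficiency)
    rows = []
    for s, sample in enumerate(samples):
        for assay, base in (("target", config.ct_base - shift[s]),
                            ("control", config.ct_base)):
            for rep in range(1, 5):
                ct = base + rng.normal(0.0, config.ct_noise_sd)
                rows.append((sample, assay, rep, ct))
    return pd.DataFrame(rows, columns=["sample", "assay", "replicate", "ct"])


def simulate_covariates(config: SimConfig) -> pd.DataFrame:
    """Round-robin sex (M/F) and batch assignment."""
    n = config.n_individuals
    sex = np.where(np.arange(n) % 2 == 0, "M", "F")
    batch = [f"b{(i % config.n_batches) + 1}" for i in range(n)]
    return pd.DataFrame({"sex": sex, "batch": batch}, index=config.sample_ids)


def simulate_cohort(config: SimConfig | None = None, **overrides) -> SimulatedCohort:
    """Generate a complete cohort; keyword overrides patch the default config."""
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)

    genotypes = simulate_genotypes(config)
    depth, bins, truth = simulate_coverage(config)
    covariates = simulate_covariates(config)

    carrier = np.zeros(config.n_individuals, dtype=bool)
    copies = np.full(config.n_individuals, 2.0)
    carrier_cols = [c for c in truth.columns if c.startswith("carrier_")]
    if carrier_cols:
        # microbiome and qPCR follow the first planted CNV (the focal locus)
        focal = carrier_cols[0].removeprefix("carrier_")
        carrier = truth[f"carrier_{focal}"].to_numpy()
        copies = truth[f"copies_{focal}"].to_numpy(dtype=float)
    asv_counts, taxonomy = simulate_microbiome(
        config, carrier, batches=covariates["batch"])
    ct_table = simulate_qpcr(config, np.maximum(copies, 1.0))

    return SimulatedCohort(
        config=config,
        genotypes=genotypes,
        snp_positions=snp_positions(config),
        depth=depth,
        bins=bins,
        asv_counts=asv_counts,
        taxonomy=taxonomy,
        covariates=covariates,
        ct_table=ct_table,
        truth=truth,
    )
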