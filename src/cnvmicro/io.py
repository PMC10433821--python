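"""Readers and writers for the plain-text interchange formats.

Everything is TSV except genotypes, which can also round-trip through a
minimal VCF (GT field only), and CNV calls/regions, which are written as
BED6+ with 0-based half-open coordinates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import Cnvr, CnvCall
from .simulate import SimulatedCohort

__all__ = [
    "write_dosage_tsv", "read_dosage_tsv",
    "write_vcf", "read_vcf",
    "write_depth_tsv", "read_depth_tsv",
    "write_calls_bed", "read_calls_bed",
    "write_cnvrs_bed",
    "write_cohort",
]


def write_dosage_tsv(genotypes: pd.DataFrame, path: str | Path) -> None:
    genotypes.rename_axis("sample").to_csv(path, sep="\t")


def read_dosage_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_vcf(genotypes: pd.DataFrame, positions: pd.DataFrame,
              path: str | Path) -> None:
    """Write a minimal diploid VCF (unphased GT only) from dosages.

    Dosage 0/1/2 becomes 0/0, 0/1, 1/1; REF/ALT are placeholder A/G.
    ``positions`` carries chrom and pos per SNP (rows match genotype
    columns).
    """
    samples = list(genotypes.index)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in positions["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for snp in genotypes.columns:
            chrom = positions.loc[snp, "chrom"]
            pos = int(positions.loc[snp, "pos"])
            gts = "\t".join(gt_map[int(genotypes.loc[s, snp])] for s in samples)
            fh.write(f"{chrom}\t{pos}\t{snp}\tA\tG\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a biallelic VCF into (dosage matrix, positions)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, pos, rows = [], [], [], []
    for i, var in enumerate(vcf):
        ids.append(var.ID or f"snp{i + 1}")
        chroms.append(var.CHROM)
        pos.append(var.POS)
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        gt = np.where(gt == 3, 2, np.where(gt == 2, 0, gt))
        rows.append(gt)
    geno = pd.DataFrame(np.array(rows).T, index=samples, columns=ids)
    positions = pd.DataFrame({"chrom": chroms, "pos": pos}, index=ids)
    return geno, positions


def write_depth_tsv(depth: pd.DataFrame, bins: pd.DataFrame,
                    path: str | Path) -> None:
    """Bins as rows (chrom, start, end) with one column per sample."""
    out = pd.concat([bins, depth.T], axis=1)
    out.rename_axis("bin").to_csv(path, sep="\t")


def read_depth_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype={"chrom": str})
    bins = raw[["chrom", "start", "end"]]
    depth = raw.drop(columns=["chrom", "start", "end"]).T
    return depth, bins


def write_calls_bed(calls: list[CnvCall], path: str | Path) -> None:
    """BED6+2: chrom, start, end, id, score=mean_ratio, strand, sample, status."""
    with open(path, "w") as fh:
        for k, c in enumerate(calls, 1):
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\tcall{k}\t"
                     f"{c.mean_ratio:.4f}\t.\t{c.sample}\t{c.status}\n")


def read_calls_bed(path: str | Path) -> list[CnvCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            calls.append(CnvCall(sample=f[6], chrom=f[0], start=int(f[1]),
                                 end=int(f[2]), status=f[7],
                                 mean_ratio=float(f[4])))
    return calls


def write_cnvrs_bed(cnvrs: list[Cnvr], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in cnvrs:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\t"
                     f"{r.carrier_count}\t.\t{r.type}\n")


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Materialise every cohort matrix as plain text; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "vcf": outdir / "genotypes.vcf",
        "depth": outdir / "depth.tsv",
        "asv": outdir / "asv_counts.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "covariates": outdir / "covariates.tsv",
        "ct": outdir / "ct_table.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_dosage_tsv(cohort.genotypes, paths["genotypes"])
    write_vcf(cohort.genotypes, cohort.snp_positions, paths["vcf"])
    write_depth_tsv(cohort.depth, cohort.bins, paths["depth"])
    cohort.asv_counts.rename_axis("sample").to_csv(paths["asv"], sep="\t")
    cohort.taxonomy.rename_axis("asv").to_csv(paths["taxonomy"], sep="\t")
    cohort.covariates.rename_axis("sample").to_csv(paths["covariates"], sep="\t")
    cohort.ct_table.to_csv(paths["ct"], sep="\t", index=False)
    cohort.truth.rename_axis("sample").to_csv(paths["truth"], sep="\t")
    return paths
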