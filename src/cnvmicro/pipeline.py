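"""End-to-end orchestration of the CNV -> microbiome analysis.

Stages, in order: cohort simulation (or user-supplied matrices) ->
depth normalisation, CNV calling, gap merging -> CNVR clustering and the
5% carrier-frequency filter -> rarefaction and alpha diversity ->
GRM, polygenic null fit and per-CNVR mixed-model tests with BH-FDR per
trait -> focal-CNVR follow-up: qPCR relative quantification and
concordance, RQ-diversity correlations, per-individual nucleotide
diversity, Whittaker beta contrast, SVM signatures with genus enrichment
and differential abundance.  Each stage logs one structured line and
intermediate artifacts can be materialised as TSV/BED for re-running any
stage in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv as cnvmod
from . import diversity as divmod_
from . import io as iomod
from . import popgen as popmod
from . import qpcr as qpcrmod
from . import signatures as sigmod
from .association import CnvAssociation, build_grm
from .simulate import SimConfig, SimulatedCohort, simulate_cohort

__all__ = ["PipelineConfig", "RunReport", "run_end_to_end"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    sim: SimConfig = field(default_factory=SimConfig)
    rarefaction_depth: int = 10_000
    gain_thr: float = 1.25
    loss_thr: float = 0.75
    min_bins: int = 2
    gap_bp: int = 10_000
    min_freq: float = 0.05
    traits: tuple[str, ...] = ("richness", "shannon")
    fdr: float = 0.05
    n_qpcr_refs: int = 3
    run_signatures: bool = True
    signature_params: dict = field(default_factory=dict)
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed != self.sim.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    seed: int
    n_samples: int
    n_cnv_calls: int
    n_cnvrs: int
    n_cnvrs_after_filter: int
    h2: dict
    top_association: dict        # per trait: cnvr, beta, p, q
    n_significant: dict          # per trait at the configured FDR
    qpcr_precision: float | None = None
    rq_correlations: dict = field(default_factory=dict)
    whittaker: dict = field(default_factory=dict)
    popgen: dict = field(default_factory=dict)
    signature: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def summary(self) -> str:
        lines = [
            f"pipeline run (seed {self.seed}, {self.n_samples} samples)",
            f"  CNV calls: {self.n_cnv_calls}  CNVRs: {self.n_cnvrs}  "
            f"after 5% filter: {self.n_cnvrs_after_filter}",
        ]
        for trait, top in self.top_association.items():
            if top:
                lines.append(
                    f"  {trait}: top {top['cnvr']}  beta={top['beta']:.3g}  "
                    f"p={top['p']:.3g}  q={top['q']:.3g}  "
                    f"(h2={self.h2[trait]:.2f}, "
                    f"{self.n_significant[trait]} significant)")
        if self.qpcr_precision is not None:
            lines.append(f"  qPCR concordance: {self.qpcr_precision:.2f}%")
        for name, (r, p) in self.rq_correlations.items():
            lines.append(f"  RQ ~ {name}: r={r:.3f} p={p:.3g}")
        if self.whittaker:
            lines.append(f"  Whittaker beta by group: "
                         + ", ".join(f"{k}={v:.3f}"
                                     for k, v in self.whittaker["by_group"].items()))
        if self.signature:
            lines.append(
                f"  signature: mean accuracy {self.signature['mean_accuracy']:.3f}, "
                f"consensus {self.signature['n_consensus']} ASVs")
        return "\n".join(lines)


def _stage(name: str, **info) -> None:
    logger.info("stage=%s %s", name,
                " ".join(f"{k}={v}" for k, v in info.items()))


def run_end_to_end(config: PipelineConfig,
                   cohort: SimulatedCohort | None = None) -> RunReport:
    """Run the full analysis on a (by default freshly simulated) cohort."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    if cohort is None:
        cohort = simulate_cohort(config.sim)
    _stage("simulate", samples=cohort.config.n_individuals,
           bins=cohort.config.n_bins, snps=cohort.config.n_snps)
    if outdir:
        iomod.write_cohort(cohort, outdir / "cohort")

    # --- CNV discovery -------------------------------------------------
    ratios = cnvmod.normalize_depth(cohort.depth, cohort.bins)
    calls = cnvmod.call_segments(ratios, gain_thr=config.gain_thr,
                                 loss_thr=config.loss_thr,
                                 min_bins=config.min_bins, gap_bp=config.gap_bp)
    cnvrs = cnvmod.build_cnvrs(calls)
    geno = cnvmod.genotype_cnvrs(calls, cnvrs, list(cohort.depth.index),
                                 min_freq=config.min_freq)
    _stage("cnv", calls=len(calls), cnvrs=len(cnvrs),
           after_filter=len(geno.cnvr_ids))
    if outdir:
        iomod.write_calls_bed(calls, outdir / "cnv_calls.bed")
        iomod.write_cnvrs_bed(cnvrs, outdir / "cnvrs.bed")
        geno.dosage.rename_axis("sample").to_csv(outdir / "cnvr_dosage.tsv", sep="\t")

    # --- diversity -----------------------------------------------------
    rng = np.random.default_rng([config.seed, 101])
    rare = divmod_.rarefy(cohort.asv_counts, depth=config.rarefaction_depth,
                          seed=rng)
    div = pd.DataFrame({"richness": divmod_.richness(rare),
                        "shannon": divmod_.shannon(rare)})
    _stage("diversity", samples=len(div), depth=config.rarefaction_depth)
    if outdir:
        div.rename_axis("sample").to_csv(outdir / "diversity.tsv", sep="\t")

    # --- association ---------------------------------------------------
    grm = build_grm(cohort.genotypes)
    top_assoc, n_sig, h2 = {}, {}, {}
    assoc_results = {}
    for trait in config.traits:
        y = div[trait].reindex(cohort.genotypes.index).dropna()
        model = CnvAssociation(y, geno.dosage.loc[y.index],
                               cohort.covariates.loc[y.index], grm)
        res = model.fit()
        assoc_results[trait] = res
        h2[trait] = res.h2
        top = res.top()
        if top is None:
            top_assoc[trait] = None
        else:
            region = geno.regions[top.name]
            top_assoc[trait] = {
                "cnvr": top.name, "chrom": region.chrom,
                "start": region.start, "end": region.end,
                "beta": float(top["beta"]), "p": float(top["p"]),
                "q": float(top["q"]),
            }
        n_sig[trait] = int(len(res.significant(config.fdr)))
        _stage("association", trait=trait, tested=len(res.table),
               h2=f"{res.h2:.3f}")
        if outdir:
            out = res.table.copy()
            for col, val in (("chrom", "chrom"), ("start", "start"), ("end", "end")):
                out[col] = [getattr(geno.regions[c], val) for c in out.index]
            out["neg_log10_p"] = -np.log10(out["p"])
            out.rename_axis("cnvr").to_csv(outdir / f"assoc_{trait}.tsv", sep="\t")

    report = RunReport(
        seed=config.seed,
        n_samples=cohort.config.n_individuals,
        n_cnv_calls=len(calls),
        n_cnvrs=len(cnvrs),
        n_cnvrs_after_filter=len(geno.cnvr_ids),
        h2=h2,
        top_association=top_assoc,
        n_significant=n_sig,
    )

    # --- focal-CNVR follow-up ------------------------------------------
    focal = top_assoc.get(config.traits[0]) or None
    status = None
    if focal is not None:
        status = geno.status[focal["cnvr"]].map(
            {"diploid": "2N", "gain": "DUP", "loss": "LOSS"})
    if status is not None and status.nunique() >= 2:
        refs = list(status.index[status == "2N"][: config.n_qpcr_refs])
        try:
            rq = qpcrmod.delta_delta_ct(cohort.ct_table, refs)
            qpcr_status = qpcrmod.classify_status(rq)
            report.qpcr_precision = qpcrmod.concordance_precision(
                status, qpcr_status)
            for trait in config.traits:
                report.rq_correlations[trait] = qpcrmod.correlate(
                    rq.rq, div[trait])
            _stage("qpcr", precision=report.qpcr_precision)
        except ValueError as exc:
            logger.warning("qPCR stage skipped: %s", exc)

        pg = popmod.popgen_table(cohort.genotypes, L=cohort.config.genome_length)
        report.popgen = {
            "mean_atajima": float(pg["atajima"].mean()),
            "mean_rtajima": float(pg["rtajima"].mean()),
            "population_pi": popmod.population_pi(
                cohort.genotypes, L=cohort.config.genome_length),
        }
        if report.rq_correlations:
            report.rq_correlations["rtajima"] = qpcrmod.correlate(
                rq.rq, pg["rtajima"])
        if outdir:
            pg.rename_axis("sample").to_csv(outdir / "popgen.tsv", sep="\t")

        two_group = status.isin(["2N", "DUP"])
        grp = status[two_group]
        counts = grp.value_counts()
        if len(counts) == 2 and counts.min() >= 3:
            rare_grp = rare.reindex(grp.index).dropna()
            beta = divmod_.whittaker_beta(rare_grp, grp.reindex(rare_grp.index))
            cmp_rich = divmod_.compare_groups(
                div["richness"].reindex(grp.index).dropna(), grp)
            report.whittaker = {"by_group": beta.to_dict(),
                                "richness_comparison_p": cmp_rich["p"]}
            _stage("beta_diversity", **beta.to_dict())

            if config.run_signatures and grp.value_counts().min() >= 5:
                clr_tab = sigmod.clr_transform(
                    cohort.asv_counts.reindex(grp.index))
                sig = sigmod.train_signature(
                    clr_tab, grp,
                    seed=int(np.random.default_rng([config.seed, 202]
                                                   ).integers(2**31)),
                    **config.signature_params)
                enr = sigmod.genus_enrichment(
                    sig.consensus, list(clr_tab.columns), cohort.taxonomy)
                da = sigmod.differential_abundance(
                    cohort.asv_counts.reindex(grp.index), grp,
                    taxonomy=cohort.taxonomy)
                report.signature = {
                    "mean_accuracy": sig.mean_accuracy,
                    "n_consensus": len(sig.consensus),
                    "top_enriched_genus": (enr.index[0] if len(enr) else None),
                    "n_da_genera": int((da["q"] < config.fdr).sum()),
                }
                _stage("signatures", accuracy=f"{sig.mean_accuracy:.3f}",
                       consensus=len(sig.consensus))
                if outdir:
                    pd.DataFrame({
                        "genus": cohort.taxonomy.reindex(sig.consensus),
                        "importance": sig.mean_importance.reindex(sig.consensus),
                        "support": sig.support.reindex(sig.consensus),
                    }).rename_axis("asv").to_csv(
                        outdir / "signature_consensus.tsv", sep="\t")
                    enr.to_csv(outdir / "genus_enrichment.tsv", sep="\t")
                    da.to_csv(outdir / "differential_abundance.tsv", sep="\t")

    if outdir:
        (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        (outdir / "report.txt").write_text(report.summary() + "\n")
    return report
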