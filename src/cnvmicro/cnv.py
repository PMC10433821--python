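"""CNV discovery from binned read depth.

Per-sample depth is normalised against a pooled baseline (per-bin median
across samples), thresholded into gain/loss segments, gap-merged, and the
resulting per-sample calls are clustered into copy-number variant regions
(CNVRs) by 50% reciprocal overlap.  Each sample is then genotyped at each
CNVR as loss / diploid / gain with the additive dosage coding 0 / 1 / 2,
and rare CNVRs (carrier frequency below 5%) are dropped.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RatioMatrix",
    "CnvCall",
    "Cnvr",
    "CnvGenotypeMatrix",
    "normalize_depth",
    "call_segments",
    "build_cnvrs",
    "genotype_cnvrs",
    "reciprocal_overlap",
    "GAP_MERGE_BP",
]

logger = logging.getLogger(__name__)

#: same-sample same-status calls closer than this are merged across the gap
GAP_MERGE_BP = 10_000


@dataclass
class RatioMatrix:
    """Samples x bins matrix of baseline-normalised depth ratios."""

    ratios: pd.DataFrame      # samples x bins; masked bins are NaN
    bins: pd.DataFrame        # chrom, start, end per bin (0-based half-open)
    masked: pd.Index          # bin ids excluded from calling

    @property
    def samples(self) -> pd.Index:
        return self.ratios.index


@dataclass(frozen=True)
class CnvCall:
    """A per-sample CNV call."""

    sample: str
    chrom: str
    start: int
    end: int
    status: str              # "gain" | "loss"
    mean_ratio: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("call end must exceed start")
        if self.status not in ("gain", "loss"):
            raise ValueError("status must be gain or loss")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Cnvr:
    """A copy-number variant region: clustered per-sample calls."""

    id: str
    chrom: str
    start: int
    end: int
    member_calls: list[CnvCall] = field(default_factory=list)

    @property
    def type(self) -> str:
        statuses = {c.status for c in self.member_calls}
        if statuses == {"gain"}:
            return "gain"
        if statuses == {"loss"}:
            return "loss"
        return "mixed"

    @property
    def carrier_count(self) -> int:
        return len({c.sample for c in self.member_calls})


@dataclass
class CnvGenotypeMatrix:
    """Samples x CNVRs status/dosage matrix after the frequency filter."""

    status: pd.DataFrame     # "loss" | "diploid" | "gain"
    dosage: pd.DataFrame     # 0 | 1 | 2 (loss / diploid / gain)
    frequency: pd.Series     # per-CNVR carrier frequency
    regions: dict[str, Cnvr]

    @property
    def cnvr_ids(self) -> list[str]:
        return list(self.status.columns)


def normalize_depth(depth: pd.DataFrame, bins: pd.DataFrame) -> RatioMatrix:
    """Normalise binned depth against the pooled per-bin median baseline.

    ratio(s, b) = depth(s, b) / median_s depth(., b), then rescaled so the
    per-sample median ratio over unmasked bins is 1.  Bins whose baseline
    is zero are masked (NaN) and excluded from calling.
    """
    if depth.shape[0] < 3:
        raise ValueError("need at least 3 samples to pool a baseline")
    if not depth.columns.equals(bins.index):
        raise ValueError("depth columns must match the bin table index")
    widths = (bins["end"] - bins["start"]).to_numpy()
    if len(set(widths.tolist())) > 1:
        raise ValueError("all bins must have the same width")

    baseline = depth.median(axis=0)
    masked = baseline.index[baseline == 0]
    if len(masked):
        logger.warning("masking %d bins with zero pooled baseline", len(masked))
    ratios = depth.div(baseline.replace(0, np.nan), axis=1)
    per_sample_median = ratios.median(axis=1)
    if (per_sample_median <= 0).any():
        raise ValueError("a sample has non-positive median ratio")
    ratios = ratios.div(per_sample_median, axis=0)
    return RatioMatrix(ratios=ratios, bins=bins.copy(), masked=masked)


def _runs(classes: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal class value as (start_idx, end_idx_excl, value)."""
    runs = []
    start = 0
    for i in range(1, len(classes) + 1):
        if i == len(classes) or classes[i] != classes[start]:
            runs.append((start, i, int(classes[start])))
            start = i
    return runs


def call_segments(ratios: RatioMatrix,
                  gain_thr: float = 1.25,
                  loss_thr: float = 0.75,
                  min_bins: int = 2,
                  gap_bp: int = GAP_MERGE_BP) -> list[CnvCall]:
    """Threshold ratios into per-sample gain/loss calls.

    Bins with ratio >= gain_thr (<= loss_thr) are classed gain (loss);
    maximal same-status runs of at least ``min_bins`` bins become calls,
    and same-sample same-status calls separated by less than ``gap_bp``
    are merged into one call spanning the gap.  Masked bins are skipped.
    """
    if not loss_thr < 1.0 < gain_thr:
        raise ValueError("thresholds must satisfy loss_thr < 1 < gain_thr")
    bins = ratios.bins
    calls: list[CnvCall] = []
    for sample, row in ratios.ratios.iterrows():
        sample_calls: list[CnvCall] = []
        for chrom, chrom_bins in bins.groupby("chrom", sort=False):
            keep = ~row[chrom_bins.index].isna().to_numpy()
            sub = chrom_bins[keep]
            vals = row[sub.index].to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            classes = np.zeros(len(vals), dtype=int)
            classes[vals >= gain_thr] = 1
            classes[vals <= loss_thr] = -1
            for i0, i1, cls in _runs(classes):
                if cls == 0 or i1 - i0 < min_bins:
                    continue
                status = "gain" if cls == 1 else "loss"
                sample_calls.append(CnvCall(
                    sample=str(sample),
                    chrom=str(chrom),
                    start=int(sub["start"].iloc[i0]),
                    end=int(sub["end"].iloc[i1 - 1]),
                    status=status,
                    mean_ratio=float(vals[i0:i1].mean()),
                ))
        calls.extend(_merge_gaps(sample_calls, gap_bp))
    return calls


def _merge_gaps(calls: list[CnvCall], gap_bp: int) -> list[CnvCall]:
    """Merge same-status calls of one sample separated by < gap_bp."""
    merged: list[CnvCall] = []
    order = sorted(calls, key=lambda c: (c.chrom, c.status, c.start))
    for call in order:
        prev = merged[-1] if merged else None
        if (prev is not None and prev.chrom == call.chrom
                and prev.status == call.status
                and call.start - prev.end < gap_bp):
            total = prev.length + call.length
            merged[-1] = CnvCall(
                sample=prev.sample, chrom=prev.chrom,
                start=prev.start, end=max(prev.end, call.end),
                status=prev.status,
                mean_ratio=(prev.mean_ratio * prev.length
                            + call.mean_ratio * call.length) / total,
            )
        else:
            merged.append(call)
    return sorted(merged, key=lambda c: (c.chrom, c.start))


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """min(|A∩B|/|A|, |A∩B|/|B|) for two half-open intervals."""
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def build_cnvrs(calls: list[CnvCall], min_ro: float = 0.5) -> list[Cnvr]:
    """Cluster calls into CNVRs by >= 50% reciprocal overlap.

    Single-linkage agglomeration: every call starts as its own cluster;
    clusters whose union extents share at least ``min_ro`` reciprocal
    overlap are merged, sweeping in coordinate order and re-scanning until
    no pair of cluster extents satisfies the predicate (a fixpoint).  The
    cluster extent is the union (min start, max end) of its members.
    """
    clusters: list[list[CnvCall]] = [[c] for c in calls]

    def extent(cluster: list[CnvCall]) -> tuple[str, int, int]:
        return (cluster[0].chrom,
                min(c.start for c in cluster),
                max(c.end for c in cluster))

    # deterministic rule: repeatedly merge the first pair of cluster
    # extents, in (chrom, start, end) order, with RO >= min_ro; the
    # fixpoint of pairwise merging is order-dependent, so the merge order
    # is part of the definition
    merged = True
    while merged:
        merged = False
        clusters.sort(key=extent)
        exts = [extent(cl) for cl in clusters]
        for i in range(len(clusters) - 1):
            ci = exts[i]
            for j in range(i + 1, len(clusters)):
                cj = exts[j]
                if cj[0] != ci[0] or cj[1] >= ci[2]:
                    break  # sorted: no later cluster can intersect i
                if reciprocal_overlap(ci[1], ci[2], cj[1], cj[2]) >= min_ro:
                    clusters[i].extend(clusters.pop(j))
                    merged = True
                    break
            if merged:
                break
    cnvrs = []
    for k, cluster in enumerate(clusters, start=1):
        chrom, start, end = extent(cluster)
        cnvrs.append(Cnvr(id=f"CNVR{k}", chrom=chrom, start=start, end=end,
                          member_calls=sorted(cluster,
                                              key=lambda c: (c.sample, c.start))))
    return cnvrs


def genotype_cnvrs(calls: list[CnvCall],
                   cnvrs: list[Cnvr],
                   samples: list[str] | pd.Index,
                   min_freq: float = 0.05) -> CnvGenotypeMatrix:
    """Genotype every sample at every CNVR and apply the frequency filter.

    A sample's status at a CNVR is the status of its member call(s) there
    (diploid if none).  A sample with both gain and loss calls inside one
    CNVR gets the status with the larger total overlapped length; exact
    ties fall back to diploid and are logged.  CNVRs carried by fewer than
    ``min_freq`` of samples (strict) are removed; the boundary is kept.
    """
    samples = list(samples)
    n = len(samples)
    status = pd.DataFrame("diploid", index=samples,
                          columns=[r.id for r in cnvrs], dtype=object)
    for region in cnvrs:
        per_sample: dict[str, dict[str, int]] = {}
        for call in region.member_calls:
            ov = min(call.end, region.end) - max(call.start, region.start)
            per_sample.setdefault(call.sample, {"gain": 0, "loss": 0})
            per_sample[call.sample][call.status] += max(ov, 0)
        for sample, lengths in per_sample.items():
            if lengths["gain"] > lengths["loss"]:
                status.loc[sample, region.id] = "gain"
            elif lengths["loss"] > lengths["gain"]:
                status.loc[sample, region.id] = "loss"
            else:
                logger.warning(
                    "sample %s has tied gain/loss overlap in %s; set diploid",
                    sample, region.id)

    frequency = (status != "diploid").sum(axis=0) / n
    keep = frequency.index[frequency >= min_freq]
    dropped = frequency.index.difference(keep)
    if len(dropped):
        logger.info("dropped %d CNVRs below carrier frequency %.2f",
                    len(dropped), min_freq)
    status = status[keep]
    dosage = status.apply(
        lambda col: col.map({"loss": 0, "diploid": 1, "gain": 2})).astype(int)
    return CnvGenotypeMatrix(
        status=status,
        dosage=dosage,
        frequency=frequency[keep],
        regions={r.id: r for r in cnvrs if r.id in set(keep)},
    )
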