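"""Relative quantification of copy number from qPCR Ct values.

The 2^-ddCt method: each sample's Ct difference between a target assay
inside the candidate CNV and a single-copy control assay (dCt) is
referenced against the mean dCt of designated diploid reference samples
(ddCt), and RQ = 2^-ddCt estimates copies/2.  Samples are then classed
2N / DUP / LOSS by RQ thresholds, compared against in-silico CNV
predictions (precision = percent concordant), and correlated with
diversity via Pearson's r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RqResult",
    "delta_delta_ct",
    "classify_status",
    "concordance_precision",
    "correlate",
]

logger = logging.getLogger(__name__)

#: replicate wells farther than this from the sample-assay median are dropped
REPLICATE_OUTLIER_CYCLES = 0.5


@dataclass
class RqResult:
    """Per-sample dCt, ddCt and RQ with the reference sample ids."""

    table: pd.DataFrame          # index sample; columns dct, ddct, rq
    reference_ids: list[str]

    @property
    def rq(self) -> pd.Series:
        return self.table["rq"]


def _clean_replicates(ct: pd.DataFrame) -> pd.DataFrame:
    """Drop replicate wells > 0.5 cycles from their sample-assay median."""
    med = ct.groupby(["sample", "assay"])["ct"].transform("median")
    keep = (ct["ct"] - med).abs() <= REPLICATE_OUTLIER_CYCLES
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropped %d outlier replicate wells", n_drop)
    return ct[keep]


def delta_delta_ct(ct: pd.DataFrame, reference_ids: list[str]) -> RqResult:
    """Compute per-sample RQ = 2^-ddCt against diploid reference samples.

    ``ct`` is long format with columns sample, assay ("target" |
    "control"), replicate, ct.  Samples missing an assay or left with
    fewer than 2 usable replicates after outlier removal are skipped with
    a log message.
    """
    required = {"sample", "assay", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    clean = _clean_replicates(ct)

    dct = {}
    for sample, grp in clean.groupby("sample"):
        means = grp.groupby("assay")["ct"].agg(["mean", "count"])
        if not {"target", "control"}.issubset(means.index):
            logger.warning("sample %s is missing an assay; skipped", sample)
            continue
        if (means.loc[["target", "control"], "count"] < 2).any():
            logger.warning("sample %s has <2 usable replicates; skipped", sample)
            continue
        dct[sample] = means.loc["target", "mean"] - means.loc["control", "mean"]
    dct = pd.Series(dct, name="dct")

    missing_refs = [r for r in reference_ids if r not in dct.index]
    if missing_refs:
        raise ValueError(f"reference samples not usable: {missing_refs}")
    ref_mean = dct.loc[list(reference_ids)].mean()
    ddct = dct - ref_mean
    table = pd.DataFrame({"dct": dct, "ddct": ddct, "rq": np.power(2.0, -ddct)})
    return RqResult(table=table, reference_ids=list(reference_ids))


def classify_status(rq: RqResult | pd.Series,
                    dup_thr: float = 1.25,
                    loss_thr: float = 0.75) -> pd.Series:
    """Class each sample 2N / DUP / LOSS from its relative quantity."""
    values = rq.rq if isinstance(rq, RqResult) else pd.Series(rq)
    status = pd.Series("2N", index=values.index, dtype=object, name="status")
    status[values >= dup_thr] = "DUP"
    status[values <= loss_thr] = "LOSS"
    return status


def concordance_precision(predicted: pd.Series, observed: pd.Series) -> float:
    """Percent of samples where the two status calls agree (2 decimals)."""
    common = predicted.index.intersection(observed.index)
    if len(common) == 0:
        raise ValueError("no samples in common between predicted and observed")
    agree = (predicted.loc[common] == observed.loc[common]).sum()
    return round(100.0 * float(agree) / len(common), 2)


def correlate(x: pd.Series | np.ndarray,
              y: pd.Series | np.ndarray) -> tuple[float, float]:
    """Pearson correlation with its two-sided t-approximation p-value."""
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        common = x.index.intersection(y.index)
        x, y = x.loc[common], y.loc[common]
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(xa) < 3:
        raise ValueError("need at least 3 paired observations")
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)
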