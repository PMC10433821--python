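"""Rarefaction and alpha/beta diversity on ASV count tables.

Samples are rarefied to a common depth (default 10,000 reads) before any
diversity index is computed.  Alpha diversity is observed richness and
the Shannon index (natural log by default); beta diversity is the
pairwise Whittaker index beta_w = S_union / mean(S_A, S_B) - 1 on
presence/absence, summarised per group as the mean over within-group
pairs.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "rarefy",
    "richness",
    "shannon",
    "whittaker_beta",
    "pairwise_whittaker",
    "compare_groups",
    "diversity_table",
]

logger = logging.getLogger(__name__)

RAREFACTION_DEPTH = 10_000


def rarefy(table: pd.DataFrame, depth: int = RAREFACTION_DEPTH,
           seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose library is below ``depth`` are dropped with a warning.
    Subsampling draws from the multivariate hypergeometric distribution,
    i.e. reads are removed at random without replacement.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    totals = table.sum(axis=1)
    keep = totals[totals >= depth].index
    dropped = table.index.difference(keep)
    if len(dropped):
        logger.warning("dropping %d samples below rarefaction depth %d: %s",
                       len(dropped), depth, list(dropped))
    if len(keep) == 0:
        raise ValueError(f"all samples fall below rarefaction depth {depth}")
    out = np.empty((len(keep), table.shape[1]), dtype=np.int64)
    for i, sample in enumerate(keep):
        counts = table.loc[sample].to_numpy(dtype=np.int64)
        out[i] = rng.multivariate_hypergeometric(counts, depth)
    return pd.DataFrame(out, index=keep, columns=table.columns)


def richness(table: pd.DataFrame) -> pd.Series:
    """Observed richness: number of ASVs with a positive count per sample."""
    return (table > 0).sum(axis=1).rename("richness")


def shannon(table: pd.DataFrame, base: float | None = None) -> pd.Series:
    """Shannon diversity H = -sum p_i log p_i per sample.

    Natural log by default; pass ``base=2`` for bits.  Zero-sum rows are
    an error because proportions are undefined.
    """
    totals = table.sum(axis=1)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero-sum samples have undefined Shannon index: {bad}")
    vals = np.array([stats.entropy(row.to_numpy(dtype=float))
                     for _, row in table.iterrows()])
    if base is not None:
        vals = vals / math.log(base)
    return pd.Series(vals, index=table.index, name="shannon")


def pairwise_whittaker(a: np.ndarray, b: np.ndarray) -> float:
    """Whittaker beta for two presence/absence profiles.

    beta_w = S_union / mean(S_a, S_b) - 1; 0 for identical profiles, 1
    for disjoint profiles of equal richness.
    """
    pa, pb = np.asarray(a) > 0, np.asarray(b) > 0
    s_a, s_b = pa.sum(), pb.sum()
    if s_a + s_b == 0:
        raise ValueError("both profiles are empty")
    s_union = (pa | pb).sum()
    return float(s_union / ((s_a + s_b) / 2.0) - 1.0)


def whittaker_beta(table: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Mean within-group pairwise Whittaker beta, one value per group."""
    groups = groups.reindex(table.index)
    out = {}
    for label, members in table.groupby(groups, sort=True):
        if len(members) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
        vals = [pairwise_whittaker(members.iloc[i].to_numpy(),
                                   members.iloc[j].to_numpy())
                for i, j in itertools.combinations(range(len(members)), 2)]
        out[label] = float(np.mean(vals))
    return pd.Series(out, name="whittaker")


def compare_groups(values: pd.Series, groups: pd.Series,
                   permutation: bool = False,
                   n_perm: int = 9999,
                   seed: int | None = None) -> dict:
    """Two-group comparison of a per-sample statistic.

    Welch's two-sample t-test by default; with ``permutation=True`` the
    p-value comes from a label-permutation null of the mean difference.
    Returns group means, SDs, sizes and the two-sided p-value.
    """
    groups = groups.reindex(values.index)
    labels = sorted(groups.dropna().unique().tolist())
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {labels}")
    x = values[groups == labels[0]].to_numpy(dtype=float)
    y = values[groups == labels[1]].to_numpy(dtype=float)
    if min(len(x), len(y)) < 3:
        raise ValueError("each group needs at least 3 samples")

    result = {
        "groups": labels,
        "means": {labels[0]: float(x.mean()), labels[1]: float(y.mean())},
        "sds": {labels[0]: float(x.std(ddof=1)), labels[1]: float(y.std(ddof=1))},
        "n": {labels[0]: int(len(x)), labels[1]: int(len(y))},
    }
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        result["p"] = 1.0 if x.mean() == y.mean() else 0.0
        result["test"] = "degenerate"
        return result
    if permutation:
        res = stats.permutation_test(
            (x, y), lambda a, b: np.mean(a) - np.mean(b),
            permutation_type="independent", n_resamples=n_perm,
            alternative="two-sided", rng=np.random.default_rng(seed))
        result["p"] = float(res.pvalue)
        result["test"] = "permutation"
    else:
        t = stats.ttest_ind(x, y, equal_var=False)
        result["p"] = float(t.pvalue)
        result["test"] = "welch"
    return result


def diversity_table(table: pd.DataFrame,
                    depth: int = RAREFACTION_DEPTH,
                    seed: int | None = None,
                    base: float | None = None) -> pd.DataFrame:
    """Rarefy then compute per-sample richness and Shannon diversity."""
    rare = rarefy(table, depth=depth, seed=seed)
    return pd.DataFrame({"richness": richness(rare), "shannon": shannon(rare, base=base)})
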