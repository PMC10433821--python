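"""Microbial signature discovery for copy-number status groups.

ASV counts are mapped to centred log-ratio (CLR) coordinates, where the
linear kernel equals the Aitchison inner product of the compositions; a
soft-margin linear SVM trained on repeated stratified 80/20 splits then
yields an explicit weight vector w per replicate.  Feature importance is
(w_k)^2; the top 5% of features per replicate are retained, and the
consensus signature is the set selected in at least half the replicates.
Downstream, the consensus is tested for genus over-representation with
a hypergeometric tail, and genus-level relative abundances are compared
between groups by Wilcoxon rank-sum with BH correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.composition import clr
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .association import bh_fdr

__all__ = [
    "clr_transform",
    "SignatureClassifier",
    "SignatureResults",
    "train_signature",
    "genus_enrichment",
    "differential_abundance",
]

logger = logging.getLogger(__name__)

COST_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


def clr_transform(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centred log-ratio transform after additive pseudocount.

    clr(s, k) = ln(x_sk + c) - mean_k ln(x_s. + c); every row sums to 0.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    vals = clr(counts.to_numpy(dtype=float) + pseudocount)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def _tune_cost(X: np.ndarray, y: np.ndarray, cost_grid, cv_folds: int,
               cv_reps: int, rng: np.random.Generator) -> float:
    """Pick C by repeated stratified k-fold CV; ties go to the smaller C."""
    n_splits = min(cv_folds, int(np.bincount(y).min()))
    if n_splits < 2:
        return cost_grid[0]
    scores = {c: [] for c in cost_grid}
    for _ in range(cv_reps):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        for tr, te in skf.split(X, y):
            for c in cost_grid:
                model = SVC(kernel="linear", C=c)
                model.fit(X[tr], y[tr])
                scores[c].append(model.score(X[te], y[te]))
    best_c, best_score = cost_grid[0], -np.inf
    for c in cost_grid:   # ascending grid: strict improvement keeps smaller C
        s = float(np.mean(scores[c]))
        if s > best_score:
            best_c, best_score = c, s
    return best_c


@dataclass
class SignatureResults:
    """Replicate accuracies, per-feature importances and the consensus set."""

    accuracies: list[float]
    costs: list[float]
    selections: list[list[str]]          # top-5% feature ids per replicate
    importance: pd.DataFrame             # replicates x features, (w_k)^2
    consensus: list[str] = field(default_factory=list)
    support: pd.Series | None = None     # per-feature replicate support

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def mean_importance(self) -> pd.Series:
        return self.importance.mean(axis=0).rename("importance")

    def summary(self) -> str:
        return (
            "Compositional-kernel SVM signature\n"
            f"  replicates: {len(self.accuracies)}   "
            f"mean test accuracy: {self.mean_accuracy:.3f}\n"
            f"  tuned costs: {self.costs}\n"
            f"  consensus features (>=50% of replicates): {len(self.consensus)}"
        )


class SignatureClassifier:
    """Soft-margin linear SVM on CLR features with replicate consensus.

    Parameters mirror the published procedure: ``n_reps`` random
    stratified train/test splits at ``train_frac``; the cost C tuned by
    ``cv_reps`` x ``cv_folds`` cross-validation on each training part;
    per-replicate importance (w_k)^2 with the top ``top_frac`` retained;
    consensus across replicates at ``consensus_frac``.
    """

    def __init__(self, clr_table: pd.DataFrame, labels: pd.Series,
                 n_reps: int = 10, train_frac: float = 0.8,
                 cost_grid=COST_GRID, cv_folds: int = 10, cv_reps: int = 10,
                 top_frac: float = 0.05, consensus_frac: float = 0.5):
        self.X = clr_table
        self.labels = labels.reindex(clr_table.index)
        classes = self.labels.value_counts()
        if len(classes) != 2:
            raise ValueError(f"need exactly two classes, got {list(classes.index)}")
        if classes.min() < 5:
            raise ValueError("each class needs at least 5 samples")
        self.n_reps = n_reps
        self.train_frac = train_frac
        self.cost_grid = tuple(sorted(cost_grid))
        self.cv_folds = cv_folds
        self.cv_reps = cv_reps
        self.top_frac = top_frac
        self.consensus_frac = consensus_frac

    def fit(self, seed: int | None = None) -> SignatureResults:
        rng = np.random.default_rng(seed)
        X = self.X.to_numpy(dtype=float)
        y, classes = pd.factorize(self.labels, sort=True)
        features = list(self.X.columns)
        n_top = math.ceil(self.top_frac * len(features))
        if n_top >= len(features):
            logger.warning("top fraction covers all %d features", len(features))
            n_top = len(features)

        accuracies, costs, selections, importances = [], [], [], []
        for _ in range(self.n_reps):
            tr, te = train_test_split(
                np.arange(len(y)), train_size=self.train_frac, stratify=y,
                random_state=int(rng.integers(2**31)))
            c = _tune_cost(X[tr], y[tr], self.cost_grid, self.cv_folds,
                           self.cv_reps, rng)
            model = SVC(kernel="linear", C=c)
            model.fit(X[tr], y[tr])
            acc = float(model.score(X[te], y[te]))
            w2 = np.ravel(model.coef_) ** 2
            top = [features[k] for k in np.argsort(w2)[::-1][:n_top]]
            accuracies.append(acc)
            costs.append(c)
            selections.append(top)
            importances.append(w2)

        importance = pd.DataFrame(importances, columns=features)
        support = pd.Series(0.0, index=features)
        for sel in selections:
            support[sel] += 1
        support /= self.n_reps
        consensus = [f for f in features if support[f] >= self.consensus_frac]
        return SignatureResults(accuracies=accuracies, costs=costs,
                                selections=selections, importance=importance,
                                consensus=consensus, support=support)


def train_signature(clr_table: pd.DataFrame, labels: pd.Series,
                    seed: int | None = None, **kwargs) -> SignatureResults:
    """Functional wrapper over :class:`SignatureClassifier`."""
    return SignatureClassifier(clr_table, labels, **kwargs).fit(seed=seed)


def genus_enrichment(selected: list[str] | set[str],
                     background: list[str] | set[str],
                     taxonomy: pd.Series) -> pd.DataFrame:
    """Hypergeometric genus over-representation of a selected ASV set.

    For each genus with at least one background member: upper-tail
    P(X >= overlap) drawing |selected| ASVs from |background| with the
    genus members as successes; BH correction across genera.
    """
    selected, background = set(selected), set(background)
    if not selected <= background:
        raise ValueError("selected set must be a subset of the background")
    tax = taxonomy.reindex(sorted(background))
    M, N = len(background), len(selected)
    rows = []
    for genus, members in tax.groupby(tax):
        k_genus = len(members)
        overlap = len(selected & set(members.index))
        p = float(stats.hypergeom.sf(overlap - 1, M, k_genus, N))
        rows.append((genus, overlap, k_genus, p))
    out = pd.DataFrame(rows, columns=["genus", "overlap", "background", "p"])
    out = out.set_index("genus").sort_values("p")
    out["q"] = bh_fdr(out["p"])
    return out


def _stars(q: float) -> str:
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


def differential_abundance(counts: pd.DataFrame, groups: pd.Series,
                           taxonomy: pd.Series | None = None) -> pd.DataFrame:
    """Genus-level two-group differential relative abundance.

    Counts are aggregated to genus if a taxonomy is given, converted to
    relative abundances, and compared by two-sided Wilcoxon rank-sum per
    genus; q-values are BH across genera and direction is the sign of the
    median difference (positive = higher in the second group, sorted
    label order).  All-zero genera are skipped.
    """
    groups = groups.reindex(counts.index)
    labels = sorted(groups.dropna().unique().tolist())
    if len(labels) != 2:
        raise ValueError(f"expected two groups, got {labels}")
    if groups.value_counts().min() < 3:
        raise ValueError("each group needs at least 3 samples")
    if taxonomy is not None:
        counts = counts.T.groupby(taxonomy.reindex(counts.columns)).sum().T
    rel = counts.div(counts.sum(axis=1), axis=0)

    rows = []
    for genus in rel.columns:
        a = rel.loc[groups == labels[0], genus].to_numpy()
        b = rel.loc[groups == labels[1], genus].to_numpy()
        if a.sum() == 0 and b.sum() == 0:
            logger.info("genus %s is all-zero; skipped", genus)
            continue
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        direction = float(np.sign(np.median(b) - np.median(a)))
        rows.append((genus, direction, p))
    out = pd.DataFrame(rows, columns=["genus", "direction", "p"]).set_index("genus")
    out["q"] = bh_fdr(out["p"]) if len(out) else np.nan
    out["stars"] = out["q"].map(_stars)
    return out.sort_values("p")
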