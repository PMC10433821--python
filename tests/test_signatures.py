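"""CLR transform, SVM signature discovery, enrichment and abundance tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cnvmicro import (clr_transform, differential_abundance, genus_enrichment,
                      train_signature)

FAST_SVM = dict(n_reps=5, cv_folds=5, cv_reps=2)


class TestClr:
    def test_equal_counts_map_to_zero(self):
        table = pd.DataFrame([[9, 9, 9, 9]])
        assert np.allclose(clr_transform(table).to_numpy(), 0.0)

    def test_rows_sum_to_zero(self, rng):
        table = pd.DataFrame(rng.integers(0, 200, size=(10, 40)))
        out = clr_transform(table)
        assert np.allclose(out.sum(axis=1), 0.0, atol=1e-9)

    def test_two_taxon_hand_case(self):
        # counts (8, 2) + pseudocount 1 -> (ln 9 - ln sqrt(27), ln 3 - ln sqrt(27))
        out = clr_transform(pd.DataFrame([[8, 2]])).iloc[0]
        expected = math.log(9) - math.log(math.sqrt(27))
        assert out.iloc[0] == pytest.approx(expected, abs=1e-4)
        assert out.iloc[1] == pytest.approx(-expected, abs=1e-4)

    def test_scale_invariance_grows_with_counts(self, rng):
        row = rng.integers(50, 500, size=30)
        a = clr_transform(pd.DataFrame([row])).to_numpy()
        b = clr_transform(pd.DataFrame([row * 10])).to_numpy()
        # pseudocount-induced distortion is small at these depths
        assert np.abs(a - b).max() < 0.05

    def test_invalid_pseudocount(self):
        with pytest.raises(ValueError):
            clr_transform(pd.DataFrame([[1, 2]]), pseudocount=0)


def planted_clr(rng, n=60, p=200, n_planted=10, shift=3.0):
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"ASV{k:04d}" for k in range(p)])
    labels = pd.Series(["2N"] * (n // 2) + ["DUP"] * (n // 2), index=X.index)
    planted = list(X.columns[:n_planted])
    X.loc[labels == "DUP", planted] += shift
    return X, labels, planted


class TestTrainSignature:
    def test_separated_classes_classified_accurately(self, rng):
        X, labels, planted = planted_clr(rng, shift=3.0, n_planted=50)
        res = train_signature(X, labels, seed=0, **FAST_SVM)
        assert res.mean_accuracy >= 0.9
        assert len(res.consensus) >= 1

    def test_planted_features_recovered(self, rng):
        X, labels, planted = planted_clr(rng, shift=2.0, n_planted=10)
        res = train_signature(X, labels, seed=1, **FAST_SVM)
        assert len(set(planted) & set(res.consensus)) >= 0.8 * len(planted)

    def test_selection_size_is_top_fraction(self, rng):
        X, labels, _ = planted_clr(rng)
        res = train_signature(X, labels, seed=2, **FAST_SVM)
        n_top = math.ceil(0.05 * X.shape[1])
        assert all(len(sel) == n_top for sel in res.selections)
        assert set(res.consensus) <= set().union(*map(set, res.selections))

    def test_importances_nonnegative_and_feature_equivariant(self, rng):
        X, labels, _ = planted_clr(rng, n=40, p=60)
        res = train_signature(X, labels, seed=3, n_reps=2, cv_folds=3,
                              cv_reps=1)
        assert (res.importance.to_numpy() >= 0).all()
        perm = list(rng.permutation(X.columns))
        res_p = train_signature(X[perm], labels, seed=3, n_reps=2, cv_folds=3,
                                cv_reps=1)
        a = res.importance.iloc[0].reindex(perm).to_numpy()
        b = res_p.importance.iloc[0].to_numpy()
        assert np.allclose(a, b, atol=1e-8)

    def test_single_class_rejected(self, rng):
        X, labels, _ = planted_clr(rng, n=20, p=30)
        with pytest.raises(ValueError):
            train_signature(X, pd.Series("2N", index=X.index))


class TestEnrichment:
    def test_single_genus_background_is_uninformative(self):
        tax = pd.Series("g1", index=[f"a{i}" for i in range(6)])
        out = genus_enrichment(["a0", "a1"], list(tax.index), tax)
        assert out.loc["g1", "p"] == pytest.approx(1.0)

    def test_urn_model_hand_case(self):
        # 10 ASVs, genus A holds 5; drawing 4, all overlap 4 from A:
        # P(X >= 4) = C(5,4) C(5,0) / C(10,4) = 5/210
        tax = pd.Series(["A"] * 5 + ["B"] * 5,
                        index=[f"a{i}" for i in range(10)])
        out = genus_enrichment(["a0", "a1", "a2", "a3"], list(tax.index), tax)
        assert out.loc["A", "p"] == pytest.approx(5 / 210)

    def test_matches_tail_enumeration(self, rng):
        # brute-force hypergeometric tail on small genera
        asvs = [f"a{i}" for i in range(20)]
        tax = pd.Series(rng.choice(["g1", "g2", "g3"], size=20), index=asvs)
        selected = list(rng.choice(asvs, size=6, replace=False))
        out = genus_enrichment(selected, asvs, tax)
        M, N = 20, 6
        for genus, row in out.iterrows():
            K, k = int(row["background"]), int(row["overlap"])
            tail = sum(math.comb(K, x) * math.comb(M - K, N - x)
                       / math.comb(M, N)
                       for x in range(k, min(K, N) + 1))
            assert row["p"] == pytest.approx(tail, rel=1e-9)

    def test_selection_outside_background_rejected(self):
        tax = pd.Series({"a": "g"})
        with pytest.raises(ValueError):
            genus_enrichment(["zzz"], ["a"], tax)

    def test_random_selection_calibration(self, rng):
        # under random draws about 5% of genera reach p < 0.05
        asvs = [f"a{i}" for i in range(200)]
        tax = pd.Series([f"g{i % 40}" for i in range(200)], index=asvs)
        flags = []
        for _ in range(100):
            sel = list(rng.choice(asvs, size=20, replace=False))
            out = genus_enrichment(sel, asvs, tax)
            flags.extend(out["p"] < 0.05)
        rate = np.mean(flags)
        assert 0.0 <= rate <= 0.10


class TestDifferentialAbundance:
    def test_duplicated_groups_give_unit_pvalues(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, size=(5, 8)),
                              index=[f"s{i}" for i in range(5)])
        both = pd.concat([counts, counts.set_axis([f"t{i}" for i in range(5)])])
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=both.index)
        out = differential_abundance(both, groups)
        # rank-sum statistic sits exactly at its null mean; the continuity
        # correction keeps the asymptotic p marginally below 1
        assert (out["p"] > 0.9).all()
        assert (out["q"] >= 0.9).all()

    def test_q_at_least_p(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, size=(12, 10)))
        groups = pd.Series(["a"] * 6 + ["b"] * 6)
        out = differential_abundance(counts, groups)
        assert (out["q"] >= out["p"] - 1e-12).all()

    def test_fold_change_detected_with_power(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            counts = pd.DataFrame(rng.integers(50, 150, size=(40, 12)))
            groups = pd.Series(["a"] * 20 + ["b"] * 20)
            counts.iloc[20:, 0] *= 5  # genus 0 five-fold up in group b
            out = differential_abundance(counts, groups)
            hits += (out.loc[0, "q"] < 0.05) and (out.loc[0, "direction"] > 0)
        assert hits >= 9

    def test_genus_aggregation_and_stars(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, size=(8, 6)),
                              columns=[f"a{i}" for i in range(6)])
        tax = pd.Series(["g1", "g1", "g2", "g2", "g3", "g3"],
                        index=counts.columns)
        groups = pd.Series(["a"] * 4 + ["b"] * 4)
        out = differential_abundance(counts, groups, taxonomy=tax)
        assert set(out.index) <= {"g1", "g2", "g3"}
        assert set(out["stars"]) <= {"", "*", "**", "***"}
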