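"""CNV calling, gap merging, CNVR clustering and genotyping."""

import numpy as np
import pandas as pd
import pytest

from cnvmicro import (SimConfig, build_cnvrs, call_segments, genotype_cnvrs,
                      normalize_depth, simulate_cohort)
from cnvmicro.cnv import CnvCall, RatioMatrix, reciprocal_overlap


def make_ratio_matrix(rows, bin_size=20_000, chrom="1"):
    """RatioMatrix from a dict sample -> list of ratios."""
    n_bins = len(next(iter(rows.values())))
    starts = np.arange(n_bins) * bin_size
    bins = pd.DataFrame({"chrom": chrom, "start": starts,
                         "end": starts + bin_size},
                        index=[f"bin{i}" for i in range(n_bins)])
    ratios = pd.DataFrame(rows, dtype=float).T
    ratios.columns = bins.index
    return RatioMatrix(ratios=ratios, bins=bins, masked=pd.Index([]))


class TestNormalize:
    def test_identical_samples_give_unit_ratios(self):
        bins = pd.DataFrame({"chrom": "1", "start": [0, 100], "end": [100, 200]},
                            index=["b0", "b1"])
        depth = pd.DataFrame([[50, 80]] * 4, columns=bins.index,
                             index=list("abcd"))
        rm = normalize_depth(depth, bins)
        assert np.allclose(rm.ratios.to_numpy(), 1.0)

    def test_zero_baseline_bins_are_masked(self):
        bins = pd.DataFrame({"chrom": "1", "start": [0, 100], "end": [100, 200]},
                            index=["b0", "b1"])
        depth = pd.DataFrame({"b0": [50, 60, 55], "b1": [0, 0, 0]},
                             index=list("abc"))
        rm = normalize_depth(depth, bins)
        assert list(rm.masked) == ["b1"]
        assert rm.ratios["b1"].isna().all()
        # masked bins produce no calls
        assert call_segments(rm, min_bins=1) == []

    def test_too_few_samples_rejected(self):
        bins = pd.DataFrame({"chrom": "1", "start": [0], "end": [100]},
                            index=["b0"])
        depth = pd.DataFrame({"b0": [50, 60]}, index=list("ab"))
        with pytest.raises(ValueError, match="3 samples"):
            normalize_depth(depth, bins)

    def test_carrier_ratio_near_1_5_on_synthetic_gain(self, cohort):
        rm = normalize_depth(cohort.depth, cohort.bins)
        carriers = cohort.truth.iloc[:, 0]
        inside = cohort.bins.index[(cohort.bins["start"] >= 1_000_000)
                                   & (cohort.bins["end"] <= 1_080_000)]
        mean_ratio = rm.ratios.loc[carriers.values, inside].mean().mean()
        assert mean_ratio == pytest.approx(1.5, rel=0.05)


class TestCallSegments:
    def test_flat_profile_yields_no_calls(self):
        rm = make_ratio_matrix({"s1": [1.0] * 10, "s2": [1.02] * 10})
        assert call_segments(rm) == []

    def test_min_bins_guards_single_bin_noise(self):
        row = [1.0] * 10
        row[4] = 1.6
        rm = make_ratio_matrix({"s1": row})
        assert call_segments(rm, min_bins=2) == []
        assert len(call_segments(rm, min_bins=1)) == 1

    def test_gap_under_10kb_merges_calls(self):
        # 4-kb bins: two gain runs separated by one neutral bin (4-kb gap)
        row = [1.5, 1.5, 1.0, 1.5, 1.5]
        rm = make_ratio_matrix({"s1": row}, bin_size=4000)
        calls = call_segments(rm, min_bins=2)
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (0, 20_000)

    def test_gap_over_10kb_stays_split(self):
        # 12-kb bins: the neutral bin makes a 12-kb gap
        row = [1.5, 1.5, 1.0, 1.5, 1.5]
        rm = make_ratio_matrix({"s1": row}, bin_size=12_000)
        assert len(call_segments(rm, min_bins=2)) == 2

    def test_status_matches_ratio_side(self):
        rm = make_ratio_matrix({"s1": [0.5, 0.5, 1.0, 1.5, 1.5, 1.0]},
                               bin_size=20_000)
        calls = call_segments(rm, min_bins=2)
        assert sorted(c.status for c in calls) == ["gain", "loss"]
        for c in calls:
            assert (c.mean_ratio > 1) == (c.status == "gain")

    def test_per_sample_independence_under_permutation(self):
        rng = np.random.default_rng(0)
        rows = {f"s{k}": rng.choice([0.5, 1.0, 1.5], size=12) for k in range(5)}
        rm = make_ratio_matrix(rows)
        perm = list(rows)[::-1]
        rm_perm = RatioMatrix(ratios=rm.ratios.loc[perm], bins=rm.bins,
                              masked=rm.masked)
        by_sample = lambda calls: {
            s: sorted((c.start, c.end, c.status) for c in calls if c.sample == s)
            for s in rows}
        assert by_sample(call_segments(rm)) == by_sample(call_segments(rm_perm))

    def test_planted_cnv_recovered_in_most_carriers(self):
        cfg = SimConfig(seed=17, mean_depth=100.0)
        cohort = simulate_cohort(cfg)
        rm = normalize_depth(cohort.depth, cohort.bins)
        calls = call_segments(rm)
        carriers = set(cohort.truth.index[cohort.truth.iloc[:, 0]])
        hit = {c.sample for c in calls
               if c.status == "gain"
               and abs(c.start - 1_000_000) <= 20_000
               and abs(c.end - 1_080_000) <= 20_000}
        assert len(hit & carriers) >= 0.9 * len(carriers)


def naive_first_pair_fixpoint(calls, min_ro=0.5):
    """Oracle: repeatedly merge the first (chrom, start, end)-ordered pair
    of cluster extents with >= min_ro reciprocal overlap, re-scanning all
    pairs from scratch after every merge."""
    clusters = [[c] for c in calls]

    def ext(cl):
        return (cl[0].chrom, min(c.start for c in cl), max(c.end for c in cl))

    while True:
        clusters.sort(key=ext)
        found = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                (ch1, s1, e1), (ch2, s2, e2) = ext(clusters[i]), ext(clusters[j])
                if ch1 == ch2 and reciprocal_overlap(s1, e1, s2, e2) >= min_ro:
                    found = (i, j)
                    break
            if found:
                break
        if not found:
            return clusters
        i, j = found
        clusters[i] += clusters.pop(j)


def partition(cnvrs_or_clusters):
    out = set()
    for item in cnvrs_or_clusters:
        members = item.member_calls if hasattr(item, "member_calls") else item
        out.add(frozenset(id(c) for c in members))
    return out


def random_calls(rng, n=20, span=1000):
    calls = []
    for k in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(10, 300))
        calls.append(CnvCall(sample=f"s{k}", chrom="1", start=start,
                             end=start + length, status="gain", mean_ratio=1.5))
    return calls


class TestBuildCnvrs:
    def test_single_call_single_region(self):
        call = CnvCall("s1", "1", 100, 200, "gain", 1.6)
        (region,) = build_cnvrs([call])
        assert (region.start, region.end) == (100, 200)
        assert region.type == "gain"

    def test_identical_intervals_collapse(self):
        calls = [CnvCall("s1", "1", 100, 200, "gain", 1.6),
                 CnvCall("s2", "1", 100, 200, "gain", 1.4)]
        (region,) = build_cnvrs(calls)
        assert region.carrier_count == 2

    def test_mixed_type_label(self):
        calls = [CnvCall("s1", "1", 100, 200, "gain", 1.6),
                 CnvCall("s2", "1", 100, 200, "loss", 0.4)]
        (region,) = build_cnvrs(calls)
        assert region.type == "mixed"

    def test_disjoint_chromosomes_never_merge(self):
        calls = [CnvCall("s1", "1", 100, 200, "gain", 1.6),
                 CnvCall("s2", "2", 100, 200, "gain", 1.6)]
        assert len(build_cnvrs(calls)) == 2

    def test_output_partitions_input(self, rng):
        calls = random_calls(rng, n=40)
        regions = build_cnvrs(calls)
        seen = [c for r in regions for c in r.member_calls]
        assert sorted(map(id, seen)) == sorted(map(id, calls))
        for r in regions:
            for c in r.member_calls:
                assert r.start <= c.start and c.end <= r.end
                assert reciprocal_overlap(c.start, c.end, r.start, r.end) > 0

    def test_matches_bruteforce_fixpoint_oracle(self, rng):
        for _ in range(50):
            calls = random_calls(rng)
            assert partition(build_cnvrs(calls)) == \
                partition(naive_first_pair_fixpoint(calls))

    def test_overlap_predicate_symmetry(self, rng):
        for _ in range(200):
            a = sorted(rng.integers(0, 1000, size=2))
            b = sorted(rng.integers(0, 1000, size=2))
            if a[0] == a[1] or b[0] == b[1]:
                continue
            assert reciprocal_overlap(*a, *b) == reciprocal_overlap(*b, *a)


class TestGenotypeCnvrs:
    def test_uncalled_sample_is_diploid(self):
        calls = [CnvCall("s1", "1", 0, 100, "gain", 1.5)]
        regions = build_cnvrs(calls)
        geno = genotype_cnvrs(calls, regions, ["s1", "s2"], min_freq=0.0)
        assert geno.status.loc["s2"].iloc[0] == "diploid"
        assert geno.dosage.loc["s2"].iloc[0] == 1
        assert geno.dosage.loc["s1"].iloc[0] == 2

    def test_frequency_filter_boundary(self):
        samples = [f"s{i}" for i in range(100)]
        rare = [CnvCall(s, "1", 0, 100, "gain", 1.5) for s in samples[:4]]
        kept = [CnvCall(s, "1", 1000, 1100, "gain", 1.5) for s in samples[:5]]
        regions = build_cnvrs(rare + kept)
        geno = genotype_cnvrs(rare + kept, regions, samples, min_freq=0.05)
        # 4/100 carriers removed, 5/100 (exactly 5%) kept
        assert len(geno.cnvr_ids) == 1
        assert geno.frequency.iloc[0] == pytest.approx(0.05)

    def test_dosage_recovers_simulation_truth(self, cohort):
        rm = normalize_depth(cohort.depth, cohort.bins)
        calls = call_segments(rm)
        regions = build_cnvrs(calls)
        geno = genotype_cnvrs(calls, regions, list(cohort.depth.index))
        planted = geno.dosage.iloc[:, 0]
        truth = 1 + cohort.truth.iloc[:, 0].astype(int)
        assert (planted == truth).mean() >= 0.95

    def test_gain_loss_tie_falls_back_to_diploid(self, caplog):
        calls = [CnvCall("s1", "1", 0, 100, "gain", 1.5),
                 CnvCall("s1", "1", 100, 200, "loss", 0.5),
                 CnvCall("s2", "1", 0, 200, "gain", 1.5)]
        regions = build_cnvrs(calls)
        assert len(regions) == 1
        geno = genotype_cnvrs(calls, regions, ["s1", "s2"], min_freq=0.0)
        assert geno.status.loc["s1"].iloc[0] == "diploid"
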