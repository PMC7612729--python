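"""Counting, normalization, differential signal, clustering and ROC."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from regdyn import (
    CountMatrix,
    GenomicInterval,
    SampleMeta,
    cluster_dynamic,
    count_fragments,
    differential_signal,
    make_analysis_bins,
    mark_expression_roc,
    normalize,
    select_dynamic_elements,
    simulate_null_counts,
)


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestBins:
    sizes = {"chr1": 100_000}

    def test_peak_within_one_bin(self):
        bins = make_analysis_bins([iv(1_500, 1_700)], self.sizes)
        assert list(bins.values()) == [iv(1_000, 2_000)]

    def test_peak_spanning_three_bins(self):
        bins = make_analysis_bins([iv(900, 2_100)], self.sizes)
        assert [b.start for b in bins.values()] == [0, 1_000, 2_000]

    def test_matches_per_bin_overlap_oracle(self):
        rng = np.random.default_rng(0)
        peaks = [
            iv(int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 90_000, 200), rng.integers(1, 5_000, 200))
        ]
        bins = make_analysis_bins(peaks, self.sizes)
        for k in range(100):
            b = iv(k * 1000, (k + 1) * 1000)
            expect = any(p.start < b.end and b.start < p.end for p in peaks)
            assert (f"chr1:{b.start}-{b.end}" in bins) == expect


class TestCountFragments:
    def test_multi_overlap_counts_both(self):
        regions = {"r1": iv(0, 100), "r2": iv(100, 200)}
        cm = count_fragments({"s1": [iv(50, 150)]}, regions)
        assert cm.counts.loc["r1", "s1"] == 1
        assert cm.counts.loc["r2", "s1"] == 1

    def test_no_overlap_no_increment(self):
        cm = count_fragments({"s1": [iv(500, 600)]}, {"r1": iv(0, 100)})
        assert cm.counts.loc["r1", "s1"] == 0

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(1)
        regions = {
            f"r{i}": iv(int(s), int(s) + int(w))
            for i, (s, w) in enumerate(
                zip(rng.integers(0, 50_000, 60), rng.integers(50, 3_000, 60))
            )
        }
        frags = [
            iv(int(s), int(s) + 200, chrom=str(rng.choice(["chr1", "chr2"])))
            for s in rng.integers(0, 50_000, 1000)
        ]
        cm = count_fragments({"s1": frags}, regions)
        for rid, r in regions.items():
            expect = sum(f.chrom == r.chrom and f.start < r.end and r.start < f.end
                         for f in frags)
            assert cm.counts.loc[rid, "s1"] == expect


def two_group_matrix(counts, depths):
    samples = [
        SampleMeta(f"s{j}", cell_type="A" if j < len(depths) // 2 else "B",
                   replicate=j % (len(depths) // 2) + 1, mark="H3K27ac",
                   library_depth=float(d))
        for j, d in enumerate(depths)
    ]
    return CountMatrix(
        counts=pd.DataFrame(
            np.asarray(counts), columns=[s.sample_id for s in samples]
        ),
        samples=samples,
    )


class TestNormalize:
    def test_equal_depths_identity_scaling(self):
        cm = normalize(two_group_matrix([[10, 20, 30, 40]], [1e6] * 4))
        assert np.allclose(cm.size_factors, 1.0)
        assert cm.normalized.iloc[0, 1] == pytest.approx(np.log2(21))

    def test_zero_count_stays_zero(self):
        cm = normalize(two_group_matrix([[0, 0, 0, 0]], [1e6, 2e6, 3e6, 4e6]))
        assert (cm.normalized.to_numpy() == 0).all()

    def test_depth_ratio_closed_form(self):
        # depths 1M/2M/4M with count 100 each; geometric mean 2M
        cm = normalize(two_group_matrix([[100, 100, 100, 100]], [1e6, 2e6, 4e6, 2e6]))
        s = np.array([0.5, 1.0, 2.0, 1.0])
        expect = np.log2(100 / s + 1)
        assert np.allclose(cm.normalized.iloc[0].to_numpy(), expect)

    def test_preserves_within_sample_rank_order(self):
        rng = np.random.default_rng(2)
        raw = rng.integers(0, 500, size=(50, 4))
        cm = normalize(two_group_matrix(raw, [1e6, 2e6, 3e6, 4e6]))
        for j in range(4):
            a = cm.counts.iloc[:, j].rank(method="average")
            b = cm.normalized.iloc[:, j].rank(method="average")
            assert (a == b).all()

    def test_zero_depth_hard_error(self):
        with pytest.raises(ValueError, match="non-positive"):
            normalize(two_group_matrix([[1, 1, 1, 1]], [0, 1e6, 1e6, 1e6]))


class TestDifferentialSignal:
    def test_identical_counts_not_dynamic(self):
        cm = normalize(two_group_matrix([[50, 50, 50, 50]] * 5, [1e6] * 4))
        d = differential_signal(cm, ("A", "B"))
        assert np.allclose(d.log2_fc, 0)
        assert not d.dynamic.any()

    def test_antisymmetric_in_contrast(self):
        cm = normalize(simulate_null_counts(300, seed=5).counts.pipe(
            lambda c: two_group_matrix(c.to_numpy(), [1e6, 1.2e6, 0.9e6, 1.1e6])
        ))
        ab = differential_signal(cm, ("A", "B"))
        ba = differential_signal(cm, ("B", "A"))
        assert np.allclose(ab.log2_fc, -ba.log2_fc)
        assert np.allclose(ab.p_value, ba.p_value)

    def test_bh_monotone(self):
        cm = normalize(simulate_null_counts(500, seed=6).counts.pipe(
            lambda c: two_group_matrix(c.to_numpy(), [1e6] * 4)
        ))
        d = differential_signal(cm, ("A", "B")).sort_values("p_value")
        assert d.adj_p_value.is_monotonic_increasing
        assert d.adj_p_value.min() >= d.p_value.min()

    def test_planted_eightfold_flagged(self):
        null = simulate_null_counts(2000, seed=3, mean=200)
        c = null.counts.copy()
        c.iloc[0, 2:4] = (c.iloc[0, 2:4] * 8).astype(int)
        cm = normalize(CountMatrix(counts=c, samples=null.samples))
        d = differential_signal(cm, ("A", "B"))
        row = d.iloc[0]
        assert row.log2_fc > 1 and row.dynamic

    def test_single_replicate_hard_error(self):
        samples = [
            SampleMeta("a1", "A", 1, "H3K27ac", 1e6),
            SampleMeta("b1", "B", 1, "H3K27ac", 1e6),
        ]
        cm = CountMatrix(
            counts=pd.DataFrame([[1, 2]], columns=["a1", "b1"]), samples=samples
        )
        with pytest.raises(ValueError, match="replicates"):
            differential_signal(normalize(cm), ("A", "B"))


class TestSelectDynamic:
    @staticmethod
    def setup_case():
        cts = ["c1", "c2", "c3"]
        rows = []
        states = {
            "everywhere": ["active", "active", "active"],
            "somewhere": ["primed", "active", "primed"],
            "never": ["primed", "neutral", "primed"],
        }
        for e, ss in states.items():
            for ct, s in zip(cts, ss):
                rows.append({"element_id": e, "cell_type": ct, "state": s})
        assignments = pd.DataFrame(rows)
        diff = pd.DataFrame(
            {"region_id": list(states), "dynamic": [True, True, True]}
        )
        return assignments, {("c1", "c2"): diff}

    def test_constitutive_excluded_somewhere_included(self):
        assignments, diffs = self.setup_case()
        got = select_dynamic_elements(assignments, diffs)
        assert got == {"somewhere"}

    def test_without_exclusion_constitutive_kept(self):
        assignments, diffs = self.setup_case()
        got = select_dynamic_elements(assignments, diffs, exclude_constitutive=False)
        assert got == {"somewhere", "everywhere"}

    def test_non_dynamic_excluded(self):
        assignments, diffs = self.setup_case()
        diffs[("c1", "c2")]["dynamic"] = [False, False, False]
        assert select_dynamic_elements(assignments, diffs) == set()


class TestClusterDynamic:
    def test_two_archetypes_perfectly_recovered(self):
        rng = np.random.default_rng(4)
        a = np.tile([0.0, 0.0, 10.0, 10.0], (30, 1)) + rng.normal(0, 0.3, (30, 4))
        b = np.tile([10.0, 10.0, 0.0, 0.0], (30, 1)) + rng.normal(0, 0.3, (30, 4))
        x = pd.DataFrame(np.vstack([a, b]))
        labels, profiles = cluster_dynamic(x, k=2, seed=0)
        truth = [0] * 30 + [1] * 30
        assert adjusted_rand_score(truth, labels) == 1.0
        assert profiles.shape == (2, 4)

    def test_k_one_single_cluster(self):
        x = pd.DataFrame(np.arange(12.0).reshape(3, 4))
        labels, _ = cluster_dynamic(x, k=1, seed=0)
        assert set(labels) == {1}

    def test_duplicate_rows_same_cluster(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame(rng.normal(size=(10, 4)))
        x.iloc[7] = x.iloc[2]
        labels, _ = cluster_dynamic(x, k=3, seed=1)
        assert labels.iloc[7] == labels.iloc[2]

    def test_seed_reproducible(self):
        rng = np.random.default_rng(6)
        x = pd.DataFrame(rng.normal(size=(50, 6)))
        l1, p1 = cluster_dynamic(x, k=4, seed=9)
        l2, p2 = cluster_dynamic(x, k=4, seed=9)
        assert (l1 == l2).all() and np.array_equal(p1.to_numpy(), p2.to_numpy())

    def test_k_exceeds_elements(self):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_dynamic(pd.DataFrame(np.zeros((3, 4))), k=5, seed=0)


class TestMarkExpressionRoc:
    @staticmethod
    def promoters(n, rng):
        idx = [f"p{i}" for i in range(n)]
        states = pd.Series("active", index=idx)
        expr = pd.Series(rng.permutation(n).astype(float), index=idx)
        return idx, states, expr

    def test_perfect_rank_correlation_auc_one(self):
        rng = np.random.default_rng(7)
        idx, states, expr = self.promoters(100, rng)
        auc = mark_expression_roc(states, expr * 2 + 5, expr, top_n=20)
        assert auc == 1.0

    def test_independent_signal_auc_half(self):
        rng = np.random.default_rng(8)
        idx, states, expr = self.promoters(2000, rng)
        signal = pd.Series(rng.normal(size=2000), index=idx)
        auc = mark_expression_roc(states, signal, expr, top_n=1000)
        assert abs(auc - 0.5) < 0.05

    def test_matches_pair_counting_oracle(self):
        idx = [f"p{i}" for i in range(6)]
        states = pd.Series("active", index=idx)
        expr = pd.Series([10, 9, 8, 3, 2, 1], index=idx, dtype=float)
        signal = pd.Series([5.0, 1.0, 4.0, 2.0, 3.0, 0.5], index=idx)
        auc = mark_expression_roc(states, signal, expr, top_n=3)
        pos, neg = idx[:3], idx[3:]
        wins = sum(
            1.0 if signal[p] > signal[q] else 0.5 if signal[p] == signal[q] else 0.0
            for p in pos for q in neg
        )
        assert auc == pytest.approx(wins / 9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        idx, states, expr = self.promoters(200, rng)
        signal = pd.Series(rng.normal(size=200), index=idx)
        a1 = mark_expression_roc(states, signal, expr, top_n=50)
        a2 = mark_expression_roc(states, np.exp(signal * 3), expr, top_n=50)
        assert a1 == pytest.approx(a2)

    def test_neutral_promoters_excluded(self):
        rng = np.random.default_rng(10)
        idx, states, expr = self.promoters(50, rng)
        states.iloc[:25] = "neutral"
        signal = expr.copy()
        auc = mark_expression_roc(states, signal, expr, top_n=10)
        assert auc == 1.0  # still perfect within the non-neutral subset
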