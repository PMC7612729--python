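"""TF cooperativity classes, regulatory potential, KS function calls and
direct-target rules."""

import numpy as np
import pandas as pd
import pytest
from math import comb, exp
from scipy import stats

from regdyn import (
    GenomicInterval,
    NarrowPeak,
    TfPeakCollection,
    call_direct_targets,
    intersect_tf_peaks,
    predict_tf_function,
    region_set_enrichment,
    regulatory_potential,
)
from regdyn.tf import hypergeom_overlap_pvalue


def pk(start, end, chrom="chr1", name="p"):
    return NarrowPeak(GenomicInterval(chrom, start, end), name=name,
                      summit_offset=(end - start) // 2)


def annot(tss_list, chrom="chr1"):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(tss_list))],
            "gene_name": [f"G{i}" for i in range(len(tss_list))],
            "chrom": chrom,
            "tss": tss_list,
            "strand": "+",
            "biotype": "protein_coding",
        }
    )


class TestIntersectTfPeaks:
    def test_disjoint_sets_only_singletons(self):
        colls = [
            TfPeakCollection("A", [pk(0, 100), pk(1000, 1100)]),
            TfPeakCollection("B", [pk(5000, 5100)]),
            TfPeakCollection("C", [pk(9000, 9100)]),
        ]
        classes, _ = intersect_tf_peaks(colls)
        counts = dict(zip(classes.label, classes["count"]))
        assert counts == {"A": 2, "B": 1, "C": 1, "A+B": 0, "A+C": 0,
                          "B+C": 0, "A+B+C": 0}

    def test_identical_sets_only_triple(self):
        peaks = [pk(0, 100), pk(1000, 1100)]
        colls = [TfPeakCollection(n, list(peaks)) for n in "ABC"]
        classes, pairwise = intersect_tf_peaks(colls)
        counts = dict(zip(classes.label, classes["count"]))
        assert counts["A+B+C"] == 2 and sum(counts.values()) == 2
        assert (pairwise.p_value < 1e-3).all() or len(pairwise) == 3

    def test_counts_partition_universe(self):
        rng = np.random.default_rng(0)
        colls = [
            TfPeakCollection(
                n,
                [pk(int(s) * 50, int(s) * 50 + 120) for s in rng.integers(0, 2000, 80)],
            )
            for n in "ABC"
        ]
        classes, _ = intersect_tf_peaks(colls)
        from regdyn import merge_intervals

        universe = merge_intervals(
            p.interval for c in colls for p in c.peaks
        )
        assert classes["count"].sum() == len(universe)

    def test_hypergeometric_matches_direct_summation(self):
        n_univ, n_a, n_b, k = 1000, 100, 100, 30
        expect = sum(
            comb(n_a, x) * comb(n_univ - n_a, n_b - x) / comb(n_univ, n_b)
            for x in range(k, min(n_a, n_b) + 1)
        )
        assert hypergeom_overlap_pvalue(n_univ, n_a, n_b, k) == pytest.approx(
            expect, rel=1e-10
        )


class TestRegulatoryPotential:
    def test_summit_at_tss_closed_form(self):
        rp = regulatory_potential(
            TfPeakCollection("T", [pk(49_900, 50_100)]), annot([50_000])
        )
        assert rp.score.item() == pytest.approx(exp(-0.5), rel=1e-12)

    def test_no_peak_within_window_zero(self):
        rp = regulatory_potential(
            TfPeakCollection("T", [pk(500_000, 500_200)]), annot([50_000])
        )
        assert rp.score.item() == 0.0

    def test_additive_over_equal_distance_peaks(self):
        one = regulatory_potential(
            TfPeakCollection("T", [pk(69_900, 70_100)]), annot([50_000])
        ).score.item()
        two = regulatory_potential(
            TfPeakCollection("T", [pk(69_900, 70_100), pk(29_900, 30_100)]),
            annot([50_000]),
        ).score.item()
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_monotone_decreasing_in_distance(self):
        scores = [
            regulatory_potential(
                TfPeakCollection("T", [pk(50_000 + d - 100, 50_000 + d + 100)]),
                annot([50_000]),
            ).score.item()
            for d in (0, 20_000, 60_000, 99_000)
        ]
        assert scores == sorted(scores, reverse=True)


class TestPredictTfFunction:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0, 1, 40)
        pot = pd.DataFrame({"gene_id": [f"g{i}" for i in range(40)],
                            "tf_name": "T", "score": scores})
        groups = {"up": [f"g{i}" for i in range(20)],
                  "unchanged": [f"g{i}" for i in range(20)]}
        out = predict_tf_function(pot, groups)
        assert out.ks_statistic.item() == 0.0 and out.p_value.item() == 1.0

    def test_complete_separation(self):
        pot = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(40)],
            "tf_name": "T",
            "score": np.r_[np.linspace(10, 20, 20), np.linspace(0, 1, 20)],
        })
        groups = {"up": [f"g{i}" for i in range(20)],
                  "unchanged": [f"g{i}" for i in range(20, 40)]}
        out = predict_tf_function(pot, groups)
        assert out.ks_statistic.item() == pytest.approx(1.0)
        # exact one-sided p for D=1 with n=m=20 equals 1/C(40,20)
        assert out.p_value.item() == pytest.approx(1 / comb(40, 20), rel=0.2)

    def test_asymptotic_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(2)
        up = rng.normal(0.7, 1.0, 20)
        unchanged = rng.normal(0.0, 1.0, 20)
        pot = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(40)],
            "tf_name": "T",
            "score": np.r_[up, unchanged],
        })
        groups = {"up": [f"g{i}" for i in range(20)],
                  "unchanged": [f"g{i}" for i in range(20, 40)]}
        out = predict_tf_function(pot, groups)
        obs_d = out.ks_statistic.item()
        pooled = np.r_[up, unchanged]
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            d = stats.ks_2samp(perm[:20], perm[20:], alternative="less").statistic
            count += d >= obs_d
        perm_p = (count + 1) / (n_perm + 1)
        mc_sd = np.sqrt(perm_p * (1 - perm_p) / n_perm)
        assert abs(out.p_value.item() - perm_p) < max(4 * mc_sd, 0.02)

    def test_small_group_flagged_unreliable(self):
        pot = pd.DataFrame({"gene_id": ["g0", "g1", "g2"], "tf_name": "T",
                            "score": [1.0, 2.0, 3.0]})
        out = predict_tf_function(pot, {"up": ["g0"], "unchanged": ["g1", "g2"]})
        assert out.unreliable.item()


class TestDirectTargets:
    annotation = annot([50_000])
    active_enh = [GenomicInterval("chr1", 69_500, 70_500)]

    @staticmethod
    def ko(gene_down=None, gene_up=None):
        genes = ["g0"]
        lfc = [0.0]
        adj = [0.9]
        if gene_down:
            lfc, adj = [-2.0], [1e-5]
        if gene_up:
            lfc, adj = [2.0], [1e-5]
        return pd.DataFrame({"gene_id": genes, "log2_fc": lfc, "adj_p": adj})

    def test_up_target_called(self):
        # down in SOX17 KO, SOX17-only peak 20 kb away on an active enhancer
        out = call_direct_targets(
            {"SOX17": [pk(69_800, 70_200)]},
            {"SOX17": self.ko(gene_down=True)},
            active_elements=self.active_enh,
            active_or_mixed_elements=self.active_enh,
            annotation=self.annotation,
        )
        assert out.to_dict("records")[0]["direction"] == "up"

    def test_neutral_element_blocks_up_call(self):
        out = call_direct_targets(
            {"SOX17": [pk(69_800, 70_200)]},
            {"SOX17": self.ko(gene_down=True)},
            active_elements=[],
            active_or_mixed_elements=[],  # peak overlaps nothing active/mixed
            annotation=self.annotation,
        )
        assert out.empty

    def test_down_target_requires_no_active_overlap(self):
        ko_up = {"PRDM1": self.ko(gene_up=True)}
        away_from_active = {"PRDM1": [pk(30_000, 30_400)]}
        out = call_direct_targets(
            away_from_active, ko_up,
            active_elements=self.active_enh,
            active_or_mixed_elements=self.active_enh,
            annotation=self.annotation,
        )
        assert out.to_dict("records")[0]["direction"] == "down"
        on_active = {"PRDM1": [pk(69_800, 70_200)]}
        out = call_direct_targets(
            on_active, ko_up,
            active_elements=self.active_enh,
            active_or_mixed_elements=self.active_enh,
            annotation=self.annotation,
        )
        assert out.empty

    def test_multi_tf_class_needs_every_ko(self):
        peaks = {"SOX17+PRDM1": [pk(69_800, 70_200)]}
        both_down = {"SOX17": self.ko(gene_down=True), "PRDM1": self.ko(gene_down=True)}
        one_down = {"SOX17": self.ko(gene_down=True), "PRDM1": self.ko()}
        assert len(call_direct_targets(
            peaks, both_down, self.active_enh, self.active_enh, self.annotation
        )) == 1
        assert call_direct_targets(
            peaks, one_down, self.active_enh, self.active_enh, self.annotation
        ).empty

    def test_missing_ko_table_skips_class(self, caplog):
        peaks = {"SOX17+TFAP2C": [pk(69_800, 70_200)]}
        with caplog.at_level("WARNING", logger="regdyn.tf"):
            out = call_direct_targets(
                peaks, {"SOX17": self.ko(gene_down=True)},
                self.active_enh, self.active_enh, self.annotation,
            )
        assert out.empty and "TFAP2C" in caplog.text


class TestRegionSetEnrichment:
    universe = [GenomicInterval("chr1", i * 1000, i * 1000 + 500) for i in range(500)]

    def test_query_subset_of_reference(self):
        query = self.universe[:40]
        ref = {"open": [GenomicInterval("chr1", 0, 60_000)]}
        out = region_set_enrichment(query, ref, self.universe)
        assert out.fraction.item() == 1.0

    def test_disjoint_reference(self):
        query = self.universe[:40]
        ref = {"far": [GenomicInterval("chr2", 0, 60_000)]}
        out = region_set_enrichment(query, ref, self.universe)
        assert out.fraction.item() == 0.0
        assert out.p_value.item() == pytest.approx(1.0)

    def test_hypergeometric_matches_summation(self):
        # universe 500, reference hits 50 universe regions, query 40, overlap 12
        query = self.universe[:40]
        ref_regions = [self.universe[i] for i in list(range(12)) + list(range(100, 138))]
        out = region_set_enrichment(query, {"r": ref_regions}, self.universe)
        expect = sum(
            comb(50, x) * comb(450, 40 - x) / comb(500, 40)
            for x in range(12, 41)
        )
        assert out.overlap.item() == 12
        assert out.p_value.item() == pytest.approx(expect, rel=1e-9)

    def test_universe_not_superset_hard_error(self):
        with pytest.raises(ValueError, match="superset"):
            region_set_enrichment(
                [GenomicInterval("chr9", 0, 10)], {"r": []}, self.universe
            )
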