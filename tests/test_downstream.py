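"""Promoter burden, divergence comparisons, concordance, and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asecross.downstream import (celltype_enrichment,
                                 compare_burden_by_category,
                                 cross_tissue_concordance,
                                 expression_divergence, promoter_windows,
                                 variant_burden)
from asecross.io_formats import TranscriptModel, VariantRecord


def tx(tid, strand, exons, chrom="1"):
    return TranscriptModel(tid, tid, "PCG", chrom, strand, exons)


class TestPromoterWindows:
    def test_plus_strand(self):
        (w,) = promoter_windows([tx("t1", "+", [(10_001, 12_000)])])
        assert (w.start, w.end) == (8_001, 10_000) and not w.truncated

    def test_minus_strand_mirror(self):
        (w,) = promoter_windows([tx("t1", "-", [(3_000, 5_000)])])
        assert (w.start, w.end) == (5_001, 7_000)

    def test_truncated_at_chromosome_start(self):
        (w,) = promoter_windows([tx("t1", "+", [(1_000, 2_000)])])
        assert (w.start, w.end) == (1, 999) and w.truncated

    def test_window_excludes_tss_base(self):
        for strand, exons in [("+", [(5_000, 6_000)]), ("-", [(5_000, 6_000)])]:
            (w,) = promoter_windows([tx("t1", strand, exons)])
            t = 5_000 if strand == "+" else 6_000
            assert not (w.start <= t <= w.end)
            assert w.start == t + 1 or w.end == t - 1


class TestVariantBurden:
    def _var(self, pos, ref="A", alt="G"):
        return VariantRecord("1", pos, ref, alt)

    def test_snvs_counted_inside_window(self):
        (w,) = promoter_windows([tx("t1", "+", [(10_001, 12_000)])])
        variants = [self._var(p) for p in (8_001, 9_000, 10_000, 10_001)]
        burden = variant_burden([w], variants)
        assert burden.loc["t1", "snv_count"] == 3

    def test_indel_lengths(self):
        (w,) = promoter_windows([tx("t1", "+", [(10_001, 12_000)])])
        variants = [self._var(9_000, "A", "ACT"),       # +2
                    self._var(9_100, "ACGTA", "A")]     # -4
        burden = variant_burden([w], variants)
        assert burden.loc["t1", "indel_count"] == 2
        assert burden.loc["t1", "mean_indel_length"] == pytest.approx(3.0)

    def test_empty_window(self):
        (w,) = promoter_windows([tx("t1", "+", [(10_001, 12_000)])])
        burden = variant_burden([w], [])
        assert burden.loc["t1"].tolist() == [0, 0, 0.0]

    def test_matches_bruteforce_membership_scan(self):
        rng = np.random.default_rng(0)
        windows = promoter_windows([
            tx(f"t{i}", "+" if i % 2 else "-",
               [(int(p), int(p) + 500)])
            for i, p in enumerate(rng.integers(3_000, 50_000, 20))
        ])
        variants = [self._var(int(p)) for p in rng.integers(1, 55_000, 500)]
        burden = variant_burden(windows, variants)
        for w in windows:
            expected = sum(w.start <= v.pos <= w.end for v in variants)
            assert burden.loc[w.transcript_id, "snv_count"] == expected


class TestBurdenComparison:
    def test_simulated_cis_excess_detected(self):
        rng = np.random.default_rng(1)
        n = 200
        burden = pd.DataFrame({
            "snv_count": np.concatenate([rng.poisson(9, n), rng.poisson(6, n)]),
            "indel_count": 0, "mean_indel_length": 0.0,
        }, index=[f"c{i}" for i in range(n)] + [f"t{i}" for i in range(n)])
        cats = pd.Series(["cis"] * n + ["trans"] * n, index=burden.index)
        table = compare_burden_by_category(burden, cats)
        row = table[(table["statistic"] == "snv_count")
                    & (table["group1"] == "cis")
                    & (table["group2"] == "trans")].iloc[0]
        assert row["median1"] > row["median2"]
        assert row["p_value"] < 0.01

    def test_identical_distributions_uniform_p(self):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(100):
            burden = pd.DataFrame({
                "snv_count": rng.poisson(7, 120),
                "indel_count": 0, "mean_indel_length": 0.0,
            }, index=[f"g{i}" for i in range(120)])
            cats = pd.Series(["cis"] * 60 + ["trans"] * 60, index=burden.index)
            t = compare_burden_by_category(burden, cats,
                                           groups=("cis", "trans"))
            ps.append(t[t["statistic"] == "snv_count"]["p_value"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_tiny_group_skipped(self):
        burden = pd.DataFrame({
            "snv_count": [1, 2, 3], "indel_count": 0,
            "mean_indel_length": 0.0,
        }, index=["a", "b", "c"])
        cats = pd.Series(["cis", "trans", "trans"], index=burden.index)
        table = compare_burden_by_category(burden, cats,
                                           groups=("cis", "trans"))
        assert table.empty


class TestExpressionDivergence:
    types = pd.Series({"p1": "PCG", "p2": "PCG", "l1": "lncRNA",
                       "u1": "TUCP"})

    def test_all_zero_degenerate(self):
        fc = pd.Series(0.0, index=self.types.index)
        out = expression_divergence(fc, self.types)
        assert out["median_pcg"] == 0 and out["median_noncoding"] == 0

    def test_sign_flip_invariance(self):
        fc = pd.Series([1.5, -0.5, 2.0, -3.0], index=self.types.index)
        a = expression_divergence(fc, self.types)
        b = expression_divergence(-fc, self.types)
        assert a["median_pcg"] == b["median_pcg"]
        assert a["median_noncoding"] == b["median_noncoding"]

    def test_stochastically_larger_group_detected(self):
        rng = np.random.default_rng(3)
        idx = [f"p{i}" for i in range(150)] + [f"l{i}" for i in range(150)]
        types = pd.Series(["PCG"] * 150 + ["lncRNA"] * 150, index=idx)
        fc = pd.Series(
            np.concatenate([rng.normal(0, 0.5, 150), rng.normal(0, 1.5, 150)]),
            index=idx)
        out = expression_divergence(fc, types)
        assert out["median_noncoding"] > out["median_pcg"]
        assert out["p_value"] < 0.01


class TestConcordance:
    def test_identical_fold_changes(self):
        fc = pd.Series([1.0, -2.0, 0.5, 3.0], index=list("abcd"))
        out = cross_tissue_concordance({"brain": fc, "liver": fc.copy()})
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0)
        assert out["n_pairs"].iloc[0] == 4

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(4)
        idx = [f"g{i}" for i in range(1000)]
        out = cross_tissue_concordance({
            "a": pd.Series(rng.normal(size=1000), index=idx),
            "b": pd.Series(rng.normal(size=1000), index=idx),
        })
        assert abs(out["pearson_r"].iloc[0]) < 0.1

    def test_insufficient_overlap_skipped(self):
        out = cross_tissue_concordance({
            "a": pd.Series([1.0, 2.0], index=["x", "y"]),
            "b": pd.Series([1.0, 2.0], index=["x", "y"]),
        })
        assert out.empty


class TestCelltypeEnrichment:
    def test_saturated_sets(self):
        bg = {f"g{i}" for i in range(100)}
        (res,) = celltype_enrichment(bg, {"ct": set(bg)}, bg)
        assert res.enrichment_score == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_hypergeometric_case(self):
        bg = {f"g{i}" for i in range(1000)}
        gene_set = {f"g{i}" for i in range(100)}
        markers = {f"g{i}" for i in range(80, 130)}  # 50 markers, overlap 20
        (res,) = celltype_enrichment(gene_set, {"ct": markers}, bg)
        assert res.overlap == 20
        assert res.expected == pytest.approx(5.0)
        assert res.enrichment_score == pytest.approx(4.0)
        assert res.p_value == pytest.approx(
            float(stats.hypergeom.sf(19, 1000, 50, 100)))

    def test_zero_overlap(self):
        bg = {f"g{i}" for i in range(100)}
        (res,) = celltype_enrichment(
            {"g1", "g2"}, {"ct": {"g90", "g91"}}, bg)
        assert res.enrichment_score == 0.0
        assert res.p_value > 0.9

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            celltype_enrichment({"a"}, {"ct": {"a"}}, set())
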