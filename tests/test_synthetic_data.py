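"""The synthetic-data generator's own contracts: determinism, Mendelian
consistency, generative means, and the reciprocal-cross origin mapping."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from asecross.io_formats import TranscriptModel
from asecross.synthetic_data import (SimConfig, random_genome,
                                     simulate_allelic_reads,
                                     simulate_count_experiment,
                                     simulate_imprinting_experiment,
                                     simulate_trio_genotypes,
                                     write_fixture_bundle)


class TestSimConfig:
    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(category_proportions={"cis": 0.5, "trans": 0.4})

    def test_bad_bias_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(maternal_bias=0.3)


class TestTrioGenotypes:
    def test_fixed_divergence_all_children_het_with_sire_alt(self):
        trio = simulate_trio_genotypes(500, p_divergent=1.0, seed=1)
        gt = trio["child_gt"].str.split("/")
        assert (gt.str.len() == 2).all()
        assert (gt.apply(set).apply(len) == 2).all()
        assert (trio["truth_paternal"] == trio["alt"]).all()
        assert (trio["truth_maternal"] == trio["ref"]).all()

    def test_shared_frequency_heterozygosity(self):
        f = 0.3
        trio = simulate_trio_genotypes(20000, p_divergent=0.0, seed=2,
                                       shared_alt_freq=f)
        het = trio["child_gt"].str.split("/").apply(set).apply(len) == 2
        expected = 2 * f * (1 - f)
        # binomial 4-sigma band
        sd = np.sqrt(expected * (1 - expected) / len(trio))
        assert abs(het.mean() - expected) < 4 * sd

    def test_determinism(self):
        a = simulate_trio_genotypes(100, 0.5, seed=3)
        b = simulate_trio_genotypes(100, 0.5, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_mendelian_consistency(self):
        trio = simulate_trio_genotypes(1000, 0.5, seed=4)
        for r in trio.itertuples(index=False):
            assert r.truth_maternal in r.mother_gt.split("/")
            assert r.truth_paternal in r.father_gt.split("/")
            assert sorted((r.truth_maternal, r.truth_paternal)) == \
                r.child_gt.split("/")


def _phase_frame(chrom, positions, maternal, paternal):
    return pd.DataFrame({
        "chrom": chrom, "pos": positions,
        "maternal_base": maternal, "paternal_base": paternal,
        "status": "phased",
    })


class TestAllelicReads:
    tx = TranscriptModel("t1", "g1", "PCG", "1", "+", [(101, 300)])

    def _genome(self, seed=10):
        return random_genome({"1": 1000}, seed=seed)

    def test_error_free_reads_carry_origin_base(self):
        genome = self._genome()
        snvs = _phase_frame("1", [200], ["A"], ["G"])
        reads = simulate_allelic_reads(snvs, self.tx, genome, 10, 0.0,
                                       seed=1, read_length=200)
        assert len(reads) == 20
        for r in reads:
            # read length 200 == transcript length: every read covers the SNV
            offset = 199 - (r.pos - 1)
            base = r.query_sequence[offset]
            assert base == ("A" if r.origin == "maternal" else "G")

    def test_snv_outside_reads_is_silent(self):
        genome = self._genome()
        snvs = _phase_frame("1", [900], ["A"], ["G"])  # outside the exon
        reads = simulate_allelic_reads(snvs, self.tx, genome, 5, 0.0,
                                       seed=2, read_length=50)
        for r in reads:
            for _, rpos in r.get_aligned_pairs(matches_only=True):
                assert rpos != 899

    def test_error_rate_binomial(self):
        genome = self._genome()
        snvs = _phase_frame("1", [200], ["A"], ["G"])
        reads = simulate_allelic_reads(snvs, self.tx, genome, 2000, 0.5,
                                       seed=3, read_length=200)
        wrong = 0
        for r in reads:
            offset = 199 - (r.pos - 1)
            base = r.query_sequence[offset]
            truth = "A" if r.origin == "maternal" else "G"
            wrong += base != truth
        n = len(reads)
        sd = np.sqrt(n * 0.5 * 0.5)
        assert abs(wrong - 0.5 * n) < 4 * sd

    def test_read_longer_than_transcript_rejected(self):
        genome = self._genome()
        with pytest.raises(ValueError, match="read length"):
            simulate_allelic_reads(
                _phase_frame("1", [200], ["A"], ["G"]), self.tx, genome,
                1, 0.0, seed=1, read_length=500)

    def test_spliced_reads_skip_introns(self):
        genome = self._genome()
        tx2 = TranscriptModel("t2", "g1", "PCG", "1", "+",
                              [(101, 200), (301, 400)])
        reads = simulate_allelic_reads(
            _phase_frame("1", [150], ["A"], ["G"]), tx2, genome, 20, 0.0,
            seed=4, read_length=150)
        for r in reads:
            for _, rpos in r.get_aligned_pairs(matches_only=True):
                assert 100 <= rpos < 200 or 300 <= rpos < 400
            if len(r.cigar_blocks) == 2:
                assert "N" in r.cigarstring


class TestCountExperiment:
    def test_group_means_follow_model(self):
        """Law-of-large-numbers check at 1,000 replicates per group."""
        cfg = SimConfig(seed=5, n_genes=12, n_f0_replicates=1000,
                        n_f1_replicates=1000, dispersion=0.01,
                        size_factor_range=(1.0, 1.0),
                        baseline_log2_mean=7, baseline_log2_sd=1)
        sim = simulate_count_experiment(cfg)
        lam = sim.truth["baseline"].to_numpy()
        c = sim.truth["cis_effect"].to_numpy()
        t = sim.truth["trans_effect"].to_numpy()
        a_cols = [col for col in sim.f0_counts if col.startswith("F0_A")]
        b_cols = [col for col in sim.f0_counts if col.startswith("F0_B")]
        assert np.allclose(sim.f0_counts[a_cols].mean(axis=1),
                           lam * 2.0 ** (c + t), rtol=0.1)
        assert np.allclose(sim.f0_counts[b_cols].mean(axis=1), lam, rtol=0.1)
        assert np.allclose(sim.f1_allele_a.mean(axis=1),
                           lam / 2 * 2.0 ** c, rtol=0.1)
        assert np.allclose(sim.f1_allele_b.mean(axis=1), lam / 2, rtol=0.1)

    def test_category_effect_mapping(self):
        cfg = SimConfig(seed=6, n_genes=600)
        truth = simulate_count_experiment(cfg).truth
        e = cfg.effect_size
        for r in truth.itertuples():
            c, t = r.cis_effect, r.trans_effect
            if r.category == "cis":
                assert abs(c) == e and t == 0
            elif r.category == "trans":
                assert c == 0 and abs(t) == e
            elif r.category == "cis_plus_trans":
                assert t == c and abs(c) == e
            elif r.category == "cis_times_trans":
                assert t == -2 * c and abs(c) == e
            elif r.category == "compensatory":
                assert t == -c and abs(c) == e
            else:
                assert c == 0 and t == 0

    def test_determinism(self):
        cfg = SimConfig(seed=7, n_genes=50)
        a = simulate_count_experiment(cfg)
        b = simulate_count_experiment(cfg)
        pd.testing.assert_frame_equal(a.f0_counts, b.f0_counts)
        pd.testing.assert_frame_equal(a.truth, b.truth)


class TestImprintingExperiment:
    def test_null_maternal_fraction_half(self):
        cfg = SimConfig(seed=8, n_genes=300, imprint_fraction=0.0,
                        baseline_log2_mean=10, baseline_log2_sd=0,
                        n_per_direction=4)
        sim = simulate_imprinting_experiment(cfg)
        axb = [l for l in sim.allele_a if "AxB" in l]
        bxa = [l for l in sim.allele_a if "BxA" in l]
        # maternal = allele B in AxB, allele A in BxA
        maternal = sim.allele_b[axb].sum().sum() + sim.allele_a[bxa].sum().sum()
        total = sim.allele_a.sum().sum() + sim.allele_b.sum().sum()
        frac = maternal / total
        assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / total)

    def test_full_bias_degenerate(self):
        cfg = SimConfig(seed=9, n_genes=100, imprint_fraction=1.0,
                        maternal_bias=1.0, n_per_direction=2)
        sim = simulate_imprinting_experiment(cfg)
        mat_genes = sim.truth.index[sim.truth["true_imprint"] == "maternal"]
        axb = [l for l in sim.allele_a if "AxB" in l]
        # maternal-only expression: the paternal (breed A in AxB) allele is 0
        assert (sim.allele_a.loc[mat_genes, axb] == 0).all().all()

    def test_reciprocal_swap_moves_breed_allele_not_bias(self):
        cfg = SimConfig(seed=10, n_genes=400, imprint_fraction=1.0,
                        maternal_bias=0.95, baseline_log2_mean=9,
                        baseline_log2_sd=0, n_per_direction=3)
        sim = simulate_imprinting_experiment(cfg)
        mat = sim.truth["true_imprint"] == "maternal"
        axb = [l for l in sim.allele_a if "AxB" in l]
        bxa = [l for l in sim.allele_a if "BxA" in l]
        # for maternally imprinted genes the dominant breed allele flips
        frac_a_axb = (sim.allele_a.loc[mat, axb].sum(axis=1)
                      / (sim.allele_a.loc[mat, axb].sum(axis=1)
                         + sim.allele_b.loc[mat, axb].sum(axis=1)))
        frac_a_bxa = (sim.allele_a.loc[mat, bxa].sum(axis=1)
                      / (sim.allele_a.loc[mat, bxa].sum(axis=1)
                         + sim.allele_b.loc[mat, bxa].sum(axis=1)))
        assert frac_a_axb.mean() < 0.2 and frac_a_bxa.mean() > 0.8


class TestFixtureBundle:
    def test_files_exist_and_parse(self, fixture_bundle):
        from asecross import allele_assignment, io_formats
        assert set(fixture_bundle) == {
            "vcf", "fasta", "sam", "gtf", "f0_counts", "f1_allele_counts",
            "design", "truth"}
        for path in fixture_bundle.values():
            assert Path(path).exists()
        assert len(io_formats.read_vcf_subset(fixture_bundle["vcf"])) > 0
        assert len(io_formats.read_gtf(fixture_bundle["gtf"])) == 30
        io_formats.read_design(fixture_bundle["design"])
        allele_assignment.AlleleCountTable.from_tsv(
            fixture_bundle["f1_allele_counts"])

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=13, n_genes=20)
        p1 = write_fixture_bundle(tmp_path / "a", cfg)
        p2 = write_fixture_bundle(tmp_path / "b", cfg)
        for key in p1:
            h1 = hashlib.sha256(Path(p1[key]).read_bytes()).hexdigest()
            h2 = hashlib.sha256(Path(p2[key]).read_bytes()).hexdigest()
            assert h1 == h2, key

    def test_different_seeds_differ(self, tmp_path):
        t1 = write_fixture_bundle(tmp_path / "a", SimConfig(seed=1, n_genes=20))
        t2 = write_fixture_bundle(tmp_path / "b", SimConfig(seed=2, n_genes=20))
        assert (Path(t1["truth"]).read_text()
                != Path(t2["truth"]).read_text())
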