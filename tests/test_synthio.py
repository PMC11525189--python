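"""Synthetic generator: geometry, barcodes, determinism, count model."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from tssreg import synthio
from tssreg.motifs import revcomp_seq, scan
from tssreg.synthio import (ConfigurationError, SynthConfig, assign_barcodes,
                            barcode_is_valid, design_fragments, generate_genes,
                            ground_truth, plant_motifs, simulate_counts)


class TestConfig:
    def test_window_not_divisible_by_fragment_length(self):
        with pytest.raises(ConfigurationError, match="divide"):
            SynthConfig(n_genes=1, upstream_window=(-199, -40))

    def test_window_overlapping_core_exclusion(self):
        with pytest.raises(ConfigurationError, match="core_exclusion"):
            SynthConfig(n_genes=1, downstream_window=(0, 160))

    def test_zero_depth_rejected(self):
        with pytest.raises(ConfigurationError, match="depth"):
            SynthConfig(n_genes=1, seq_depth=0)

    def test_zero_genes_rejected(self):
        with pytest.raises(ConfigurationError, match="n_genes"):
            SynthConfig(n_genes=0)


class TestGenerateGenes:
    def test_deterministic_given_seed(self):
        cfg = SynthConfig(n_genes=10, rng_seed=1)
        g1, genome1 = generate_genes(cfg)
        g2, genome2 = generate_genes(cfg)
        assert g1 == g2 and genome1 == genome2
        assert len(g1) == 10

    def test_seed_changes_genome(self):
        _, genome1 = generate_genes(SynthConfig(n_genes=10, rng_seed=1))
        _, genome2 = generate_genes(SynthConfig(n_genes=10, rng_seed=2))
        assert genome1 != genome2

    def test_strands_roughly_balanced_and_distances_binned(self):
        cfg = SynthConfig(n_genes=400, rng_seed=3)
        genes, _ = generate_genes(cfg)
        frac_plus = np.mean([g.strand == "+" for g in genes])
        assert 0.4 < frac_plus < 0.6
        assert all(0 <= g.tss_to_atg < 500 for g in genes)


class TestDesignFragments:
    def test_default_geometry_offsets(self):
        cfg = SynthConfig(n_genes=1, rng_seed=0)
        genes, genome = generate_genes(cfg)
        frags = design_fragments(genes, genome, cfg)
        assert [(f.side, f.offset) for f in frags] == [
            ("upstream", -200), ("downstream", 40), ("downstream", 200)]
        assert all(len(f.sequence) == 160 for f in frags)

    def test_one_to_two_composition(self):
        cfg = SynthConfig(n_genes=40, rng_seed=0)
        genes, genome = generate_genes(cfg)
        frags = design_fragments(genes, genome, cfg)
        sides = pd.Series([f.side for f in frags]).value_counts()
        assert sides["upstream"] == 40 and sides["downstream"] == 80

    def test_minus_strand_fragment_is_reverse_complemented(self):
        cfg = SynthConfig(n_genes=20, rng_seed=5)
        genes, genome = generate_genes(cfg)
        gene = next(g for g in genes if g.strand == "-")
        frags = [f for f in design_fragments([gene], genome, cfg) if f.offset == 40]
        genomic = genome[gene.chrom][gene.tss_pos - 199:gene.tss_pos - 39]
        assert frags[0].sequence == revcomp_seq(genomic)

    def test_fragment_beyond_chromosome_skipped(self, caplog):
        cfg = SynthConfig(n_genes=1, rng_seed=0)
        genes, genome = generate_genes(cfg)
        short = {genes[0].chrom: genome[genes[0].chrom][:cfg.tss_flank + 100]}
        with caplog.at_level("WARNING"):
            frags = design_fragments(genes, short, cfg)
        assert len(frags) < 3


class TestBarcodes:
    def test_pattern_space_size(self):
        assert (3 * 4 * 4) ** 5 == 254_803_968

    def test_all_barcodes_valid_and_unique(self):
        cfg = SynthConfig(n_genes=1, barcodes_per_fragment=3, rng_seed=0)
        bm = assign_barcodes(["a", "b"], cfg)
        assert len(bm) == 6
        assert bm["barcode"].is_unique
        assert bm["barcode"].map(barcode_is_valid).all()

    def test_first_triplet_base_never_t(self):
        assert not barcode_is_valid("TAAAAAAAAAAAAAA")
        assert barcode_is_valid("AAAAAAAAAAAAAAA")
        assert not barcode_is_valid("AAAA")

    def test_exceeding_pattern_space_is_an_error(self):
        cfg = SynthConfig(n_genes=1, barcodes_per_fragment=2, rng_seed=0)
        object.__setattr__(cfg, "barcode_triplets", 1)  # shrink space to 48
        with pytest.raises(ConfigurationError, match="exceed"):
            assign_barcodes([f"f{i}" for i in range(30)], cfg)

    def test_deterministic(self):
        cfg = SynthConfig(n_genes=1, rng_seed=9)
        assert assign_barcodes(["x"], cfg).equals(assign_barcodes(["x"], cfg))


class TestGroundTruth:
    def test_activity_is_copies_times_effect_without_noise(self):
        cfg = SynthConfig(n_genes=30, fragment_noise_sd=0.0, rng_seed=2)
        genes, genome = generate_genes(cfg)
        genome = plant_motifs(genes, genome, cfg)
        frags = design_fragments(genes, genome, cfg)
        gt = ground_truth(frags, cfg)
        real = gt[~gt["is_control"]]
        np.testing.assert_allclose(real["activity_downstream"],
                                   real["copies"] * 0.585, atol=1e-12)
        np.testing.assert_allclose(real["activity_upstream"], 0.0, atol=1e-12)

    def test_copies_match_rescan(self):
        cfg = SynthConfig(n_genes=20, rng_seed=4)
        genes, genome = generate_genes(cfg)
        genome = plant_motifs(genes, genome, cfg)
        frags = design_fragments(genes, genome, cfg)
        gt = ground_truth(frags, cfg)
        for f in frags:
            assert gt.loc[f.fragment_id, "copies"] == len(scan(f.sequence, "YVGATCBR"))

    def test_activity_cap_saturates(self):
        cfg = SynthConfig(n_genes=30, fragment_noise_sd=0.0, activity_cap=0.5, rng_seed=2)
        genes, genome = generate_genes(cfg)
        genome = plant_motifs(genes, genome, cfg)
        gt = ground_truth(design_fragments(genes, genome, cfg), cfg)
        assert gt["activity_downstream"].max() <= 0.5 + 1e-12


class TestSimulateCounts:
    @staticmethod
    def _single_fragment_setup(n_barcodes, **kw):
        cfg = SynthConfig(n_genes=1, barcodes_per_fragment=n_barcodes, **kw)
        truth = pd.DataFrame({"copies": [0], "is_control": [False],
                              "activity_downstream": [0.0], "activity_upstream": [0.0]},
                             index=pd.Index(["fX"], name="fragment_id"))
        bm = assign_barcodes(["fX"], cfg)
        return cfg, truth, bm

    def test_mean_count_matches_depth_times_proportion(self):
        # law-of-large-numbers check at 10,000 draws, dispersion -> 0
        cfg, truth, bm = self._single_fragment_setup(
            10_000, nb_dispersion=0.0, seq_depth=1_000_000, n_replicates=1, rng_seed=0)
        dna, rna = simulate_counts(bm, truth, cfg)
        mu = cfg.seq_depth / 10_000          # dna_prop = 1 for the only fragment
        se = np.sqrt(mu / 10_000)
        assert abs(rna["rep1"].mean() - mu) < 3 * se

    def test_activity_one_doubles_normalised_counts(self):
        cfg = SynthConfig(n_genes=1, barcodes_per_fragment=4000, nb_dispersion=1e-13,
                          seq_depth=4_000_000, n_replicates=1, rng_seed=1)
        truth = pd.DataFrame(
            {"copies": [0, 0], "is_control": [False, False],
             "activity_downstream": [0.0, 1.0], "activity_upstream": [0.0, 0.0]},
            index=pd.Index(["fA", "fB"], name="fragment_id"))
        bm = assign_barcodes(["fA", "fB"], cfg)
        dna, rna = simulate_counts(bm, truth, cfg)
        frag = bm.set_index("barcode")["fragment_id"]
        per_frag = rna["rep1"].groupby(frag.loc[rna.index].to_numpy()).mean()
        prop = dna / dna.sum()
        ratio = (per_frag["fB"] / prop["fB"]) / (per_frag["fA"] / prop["fA"])
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_same_seed_gives_identical_tables(self):
        cfg, truth, bm = self._single_fragment_setup(100, rng_seed=3)
        dna1, rna1 = simulate_counts(bm, truth, cfg)
        dna2, rna2 = simulate_counts(bm, truth, cfg)
        assert dna1.equals(dna2) and rna1.equals(rna2)

    def test_replicates_differ(self):
        cfg, truth, bm = self._single_fragment_setup(100, n_replicates=2, rng_seed=3)
        _, rna = simulate_counts(bm, truth, cfg)
        assert not rna["rep1"].equals(rna["rep2"])


class TestLibraryBundle:
    def test_geometry_conservation(self, small_config, small_lib):
        assert len(small_lib.fragments) == small_config.n_genes * 3
        assert len(small_lib.barcode_map) == (
            (len(small_lib.fragments) + small_config.n_controls)
            * small_config.barcodes_per_fragment)

    def test_bit_identical_regeneration(self, small_config, small_lib):
        again = synthio.simulate_library(small_config, "downstream")
        assert again.truth.equals(small_lib.truth)
        assert again.rna_counts.equals(small_lib.rna_counts)
        assert again.genome == small_lib.genome

    def test_write_library_round_trip(self, small_lib, tmp_path):
        synthio.write_library(small_lib, tmp_path)
        from Bio import SeqIO
        recs = list(SeqIO.parse(tmp_path / "fragments.fasta", "fasta"))
        assert len(recs) == len(small_lib.fragments)
        bm = pd.read_csv(tmp_path / "barcode_map.tsv", sep="\t")
        assert len(bm) == len(small_lib.barcode_map)


class TestGeneLevelSimulators:
    def test_expression_mean_linear_in_count(self):
        counts = synthio.simulate_motif_counts(20_000, seed=0)
        expr = synthio.simulate_expression(counts, slope=0.4, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(expr, 0.4 * counts, atol=1e-12)

    def test_allele_effect_confined_to_window(self):
        expr, alleles, offsets = synthio.simulate_allele_data(
            n_genes=50, n_samples=40, noise_sd=0.0, seed=1)
        in_win = (offsets >= 1) & (offsets <= 500)
        for g in expr.index:
            diff = expr.loc[g][alleles.loc[g] == 1].mean() - \
                expr.loc[g][alleles.loc[g] == 0].mean()
            if alleles.loc[g].nunique() < 2:
                continue
            assert diff == pytest.approx(0.5 if in_win[g] else 0.0, abs=1e-9)
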