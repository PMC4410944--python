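"""Generator correctness: invariants, determinism, and recovery of the
configured enrichment folds, allelic biases and expression fractions."""
import dataclasses

import numpy as np
import pytest

from imprintscan.config import MarkConfig, demo_config, random_panel_config
from imprintscan.model import MATERNAL
from imprintscan.snps import SnpIndex
from imprintscan.synthetic_data import (
    build_genome,
    simulate_chip_track,
    simulate_rnaseq,
)

from conftest import tiny_config


def _hap_diffs(genome, chrom):
    m = np.frombuffer(genome.maternal_seq[chrom].encode(), dtype="S1")
    p = np.frombuffer(genome.paternal_seq[chrom].encode(), dtype="S1")
    return set(np.flatnonzero(m != p).tolist())


class TestBuildGenome:
    def test_haplotypes_differ_exactly_at_snp_table(self):
        cfg = demo_config(seed=1)
        cfg.chrom_lengths = {"chr1": 100_000, "chr2": 100_000}
        cfg.genes_per_chrom = 10
        cfg.n_imprinted = 2
        cfg.n_ko_disrupted = 1
        cfg.ervk_per_chrom = 2
        cfg.line_per_chrom = 2
        cfg.intergenic_cgis_per_chrom = 1
        genome = build_genome(cfg)
        genome.validate()
        for chrom in genome.chrom_names:
            table = {s.pos for s in genome.snps if s.chrom == chrom}
            assert _hap_diffs(genome, chrom) == table
        # 200 kb at 1/500 => ~400 background SNPs plus a few forced DMR SNPs
        assert 300 <= len(genome.snps) <= 520

    def test_zero_snp_density_gives_identical_haplotypes(self):
        genome = build_genome(tiny_config(snp_rate=0.0))
        assert genome.snps == []
        assert genome.maternal_seq == genome.paternal_seq

    def test_same_seed_reproduces_genome_and_reads(self):
        cfg_a, cfg_b = tiny_config(seed=9), tiny_config(seed=9)
        ga, gb = build_genome(cfg_a), build_genome(cfg_b)
        assert ga.maternal_seq == gb.maternal_seq
        assert ga.paternal_seq == gb.paternal_seq
        assert ga.snps == gb.snps
        assert ga.annotations.genes == gb.annotations.genes
        assert simulate_chip_track(ga, "ATRX", cfg_a) == simulate_chip_track(gb, "ATRX", cfg_b)

    def test_each_dmr_contains_snps_and_sits_inside_its_gene(self, tiny_genome):
        idx = SnpIndex(tiny_genome.snps)
        genes = {g.name: g for g in tiny_genome.annotations.genes}
        for dmr in tiny_genome.annotations.dmrs:
            pos, _, _ = idx.in_span(dmr.chrom, dmr.start, dmr.end)
            assert len(pos) >= 1
            host = genes[dmr.regulated_genes[0]]
            assert host.start <= dmr.start and dmr.end <= host.end

    def test_unknown_mark_rejected(self, tiny_genome):
        with pytest.raises(ValueError, match="unknown mark"):
            simulate_chip_track(tiny_genome, "H3K36me3", tiny_config())


class TestChipTrack:
    def test_depth_conservation(self, tiny_genome):
        reads = simulate_chip_track(tiny_genome, "H3K9me3", tiny_config(), depth=7_123)
        assert len(reads) == 7_123

    def test_fold_recovery_against_poisson_oracle(self):
        """With enrichment restricted to DMRs, the in/out read-density ratio
        recovers the configured fold within Poisson error."""
        cfg = tiny_config(seed=21, chip_depth=100_000)
        cfg.marks["H3K9me3"] = MarkConfig(fold={"dmr": 8.0}, dmr_bias=0.9)
        genome = build_genome(cfg)
        reads = simulate_chip_track(genome, "H3K9me3", cfg)
        dmrs = genome.annotations.dmrs
        in_bp = sum(len(d) for d in dmrs)
        total_bp = sum(genome.chrom_sizes.values())
        n_in = sum(any(d.overlaps(r.chrom, r.start, r.start + 1) for d in dmrs)
                   for r in reads)
        n_out = len(reads) - n_in
        ratio = (n_in / in_bp) / (n_out / (total_bp - in_bp))
        # Poisson counting error: sd(ratio)/ratio ~ 1/sqrt(n_in)
        fold = cfg.marks["H3K9me3"].fold_for("dmr")
        assert abs(ratio - fold) < 4 * fold / np.sqrt(n_in)

    def test_input_track_is_uniform(self):
        cfg = tiny_config(seed=22, chip_depth=100_000)
        genome = build_genome(cfg)
        reads = simulate_chip_track(genome, "input", cfg)
        dmrs = genome.annotations.dmrs
        in_bp = sum(len(d) for d in dmrs)
        total_bp = sum(genome.chrom_sizes.values())
        n_in = sum(any(d.overlaps(r.chrom, r.start, r.start + 1) for d in dmrs)
                   for r in reads)
        expected = len(reads) * in_bp / total_bp
        assert abs(n_in - expected) < 4 * np.sqrt(expected)

    def test_full_bias_sends_every_dmr_read_to_methylated_allele(self):
        cfg = tiny_config(seed=5)
        cfg.marks["H3K9me3"] = MarkConfig(fold={"dmr": 8.0}, dmr_bias=1.0)
        genome = build_genome(cfg)
        idx = SnpIndex(genome.snps)
        reads = simulate_chip_track(genome, "H3K9me3", cfg, depth=20_000)
        checked = 0
        for dmr in genome.annotations.dmrs:
            meth_hap = 0 if dmr.methylated_parent == MATERNAL else 1
            for r in reads:
                if not dmr.overlaps(r.chrom, r.start, r.end) or not r.bases_at_snps:
                    continue
                for pos, base in r.bases_at_snps.items():
                    p, mb, pb = idx.in_span(r.chrom, pos, pos + 1)
                    assert base == (mb[0] if meth_hap == 0 else pb[0])
                    checked += 1
        assert checked > 100

    def test_allelic_truth_tracks_configured_bias(self):
        """Over >=1e4 DMR reads with bias b the methylated-allele fraction is
        within 3*sqrt(b(1-b)/n) of b."""
        cfg = tiny_config(seed=6, chip_depth=200_000)
        b = cfg.marks["H3K9me3"].dmr_bias
        genome = build_genome(cfg)
        reads = simulate_chip_track(genome, "H3K9me3", cfg)
        hits = []
        for dmr in genome.annotations.dmrs:
            meth_hap = 0 if dmr.methylated_parent == MATERNAL else 1
            hits += [r.haplotype == meth_hap for r in reads
                     if dmr.overlaps(r.chrom, r.start, r.end)]
        n = len(hits)
        assert n >= 10_000
        assert abs(np.mean(hits) - b) < 3 * np.sqrt(b * (1 - b) / n)


class TestRnaSeq:
    def test_reads_come_only_from_expressed_genes_with_correct_strand(self):
        cfg = tiny_config(seed=7)
        genome = build_genome(cfg)
        batch = simulate_rnaseq(genome, "WT", "polyA+", cfg)
        genes = {(g.chrom, g.start): g for g in genome.annotations.genes}
        spans = [(g.chrom, g.start, g.end, g.strand) for g in genome.annotations.genes
                 if g.expressed]
        for read in batch:
            host = [s for s in spans if s[0] == read.chrom and s[1] <= read.start
                    and read.end <= s[2]]
            assert len(host) == 1
            # dUTP library: read strand opposite to transcript strand
            assert read.strand != host[0][3]

    def test_depth_conservation_and_determinism(self, tiny_genome):
        cfg = tiny_config()
        a = simulate_rnaseq(tiny_genome, "WT", "polyA+", cfg, depth=33_000)
        b = simulate_rnaseq(tiny_genome, "WT", "polyA+", cfg, depth=33_000)
        assert len(a) == 33_000
        assert np.array_equal(a.start, b.start) and np.array_equal(a.hap, b.hap)

    def test_maternal_fraction_zero_yields_no_maternal_reads(self):
        cfg = tiny_config(seed=8)
        genome = build_genome(cfg)
        g0 = genome.annotations.genes[0]
        genome.annotations.genes[0] = dataclasses.replace(g0, maternal_fraction=0.0)
        batch = simulate_rnaseq(genome, "WT", "polyA+", cfg)
        haps = batch.hap[batch.gene_idx == batch.genes.index(genome.annotations.genes[0])]
        assert len(haps) > 0 and (haps == 1).all()

    def test_skew_recovery_bernoulli_oracle(self):
        cfg = random_panel_config(seed=13, n_genes=10, n_imprinted=2,
                                  reads_per_gene=400)
        genome = build_genome(cfg)
        batch = simulate_rnaseq(genome, "WT", "polyA+", cfg)
        for gi, gene in enumerate(batch.genes):
            f = gene.maternal_fraction
            haps = batch.hap[batch.gene_idx == gi]
            n = len(haps)
            assert n >= 200
            if 0 < f < 1:
                assert abs((haps == 0).mean() - f) < 3 * np.sqrt(f * (1 - f) / n)

    def test_rejects_unknown_condition_and_fraction(self, tiny_genome):
        with pytest.raises(ValueError):
            simulate_rnaseq(tiny_genome, "HET", "polyA+", tiny_config())
        with pytest.raises(ValueError):
            simulate_rnaseq(tiny_genome, "WT", "total", tiny_config())
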