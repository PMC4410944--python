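"""Parental read assignment, skew statistics and imprinting/disruption
calls, including equivalence of the vectorized and per-read counting paths."""
import dataclasses

import numpy as np
import pytest

from imprintscan.allelic import (
    AllelicCount,
    assign_read,
    call_imprinting,
    compare_conditions,
    count_allelic_chip,
    count_allelic_rna,
    count_allelic_rna_batch,
    filter_informative,
    random_gene_baseline,
)
from imprintscan.config import MarkConfig, random_panel_config
from imprintscan.model import GeneModel, GenomeInterval, ReadRecord, SnpRecord, swap_parents
from imprintscan.snps import SnpIndex
from imprintscan.synthetic_data import (
    build_genome,
    expected_allele_table,
    simulate_chip_track,
    simulate_rnaseq,
)

from conftest import tiny_config

SNPS = SnpIndex([
    SnpRecord("chr1", 120, "A", "G"),
    SnpRecord("chr1", 140, "C", "T"),
    SnpRecord("chr1", 400, "G", "A"),
])


class TestAssignRead:
    def test_single_snp_maternal_base(self):
        read = ReadRecord("chr1", 100, 150, "+", bases_at_snps={120: "A", 140: "C"})
        assert assign_read(read, SNPS) == "maternal"

    def test_conflicting_votes_are_ambiguous(self):
        read = ReadRecord("chr1", 100, 150, "+", bases_at_snps={120: "A", 140: "T"})
        assert assign_read(read, SNPS) == "ambiguous"

    def test_no_snp_overlap_is_uninformative(self):
        read = ReadRecord("chr1", 200, 250, "+")
        assert assign_read(read, SNPS) == "uninformative"

    def test_all_neither_bases_are_ambiguous(self):
        read = ReadRecord("chr1", 100, 150, "+", bases_at_snps={120: "T", 140: "G"})
        assert assign_read(read, SNPS) == "ambiguous"

    def test_simulated_assignments_match_ground_truth(self):
        """Without sequencing error every informative call matches the
        haplotype the read was drawn from."""
        cfg = tiny_config(seed=11)
        genome = build_genome(cfg)
        idx = SnpIndex(genome.snps)
        reads = simulate_chip_track(genome, "H3K9me3", cfg, depth=30_000)
        informative = matched = 0
        for r in reads:
            call = assign_read(r, idx)
            if call in ("maternal", "paternal"):
                informative += 1
                matched += (call == "maternal") == (r.haplotype == 0)
        assert informative > 500
        assert matched / informative > 0.999


class TestChipCounting:
    def test_full_bias_gives_pure_skew(self):
        cfg = tiny_config(seed=12)
        cfg.marks["H3K9me3"] = MarkConfig(fold={"dmr": 8.0}, dmr_bias=1.0)
        genome = build_genome(cfg)
        idx = SnpIndex(genome.snps)
        reads = simulate_chip_track(genome, "H3K9me3", cfg, depth=30_000)
        dmr = next(d for d in genome.annotations.dmrs if d.methylated_parent == "maternal")
        count = count_allelic_chip(reads, dmr, idx)
        assert count.informative > 30
        assert count.skew_maternal == 1.0

    def test_input_track_is_balanced(self):
        cfg = tiny_config(seed=13, chip_depth=120_000)
        genome = build_genome(cfg)
        idx = SnpIndex(genome.snps)
        reads = simulate_chip_track(genome, "input", cfg)
        dmr = genome.annotations.dmrs[0]
        count = count_allelic_chip(reads, dmr, idx)
        n = count.informative
        assert abs(count.skew_maternal - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_peak_mask_excluding_snps_leaves_skew_undefined(self):
        reads = [ReadRecord("chr1", 110, 160, "+", bases_at_snps={120: "A", 140: "C"})]
        region = GenomeInterval("chr1", 100, 500)
        mask = GenomeInterval("chr1", 300, 350)
        count = count_allelic_chip(reads, region, SNPS, peak_mask=mask)
        assert count.informative == 0
        assert count.skew_maternal is None

    def test_conservation_of_read_categories(self):
        cfg = tiny_config(seed=14)
        genome = build_genome(cfg)
        idx = SnpIndex(genome.snps)
        reads = simulate_chip_track(genome, "ATRX", cfg)
        dmr = genome.annotations.dmrs[0]
        count = count_allelic_chip(reads, dmr, idx)
        overlapping = sum(dmr.overlaps(r.chrom, r.start, r.end) for r in reads)
        total = count.maternal + count.paternal + count.ambiguous + count.uninformative
        assert total == overlapping

    def test_swapping_parent_labels_mirrors_skew(self):
        cfg = tiny_config(seed=15)
        genome = build_genome(cfg)
        idx = SnpIndex(genome.snps)
        swapped = SnpIndex(swap_parents(genome.snps))
        reads = simulate_chip_track(genome, "H3K9me3", cfg)
        for dmr in genome.annotations.dmrs:
            c = count_allelic_chip(reads, dmr, idx)
            c_sw = count_allelic_chip(reads, dmr, swapped)
            if c.informative:
                assert c_sw.skew_maternal == pytest.approx(1 - c.skew_maternal)


class TestRnaCounting:
    def test_dutp_convention_counts_antisense_reads_only(self):
        gene = GeneModel("chr1", 100, 600, "+", "g")
        anti = ReadRecord("chr1", 110, 160, "-", bases_at_snps={120: "A", 140: "C"})
        sense = ReadRecord("chr1", 110, 160, "+", bases_at_snps={120: "A", 140: "C"})
        count = count_allelic_rna([anti, sense], gene, SNPS, "dUTP")
        assert (count.maternal, count.paternal) == (1, 0)
        count_same = count_allelic_rna([anti, sense], gene, SNPS, "same")
        assert count_same.maternal == 1

    def test_overlapping_antisense_pair_partitions_by_strand(self):
        """A Commd1/Zrsr1-like arrangement: an antisense gene nested in a
        host gene; strand separates their reads."""
        host = GeneModel("chr1", 100, 900, "+", "host")
        nested = GeneModel("chr1", 300, 600, "-", "nested")
        host_reads = [ReadRecord("chr1", 380, 430, "-", bases_at_snps={400: "G"})
                      for _ in range(4)]
        nested_reads = [ReadRecord("chr1", 380, 430, "+", bases_at_snps={400: "A"})
                        for _ in range(3)]
        reads = host_reads + nested_reads
        c_host = count_allelic_rna(reads, host, SNPS, "dUTP")
        c_nested = count_allelic_rna(reads, nested, SNPS, "dUTP")
        assert (c_host.maternal, c_host.paternal) == (4, 0)
        assert (c_nested.maternal, c_nested.paternal) == (0, 3)

    def test_gene_without_snps_is_uninformative(self):
        gene = GeneModel("chr2", 100, 600, "+", "g")
        reads = [ReadRecord("chr2", 110, 160, "-")]
        assert count_allelic_rna(reads, gene, SNPS, "dUTP").informative == 0

    def test_batch_path_equals_per_read_path(self):
        cfg = random_panel_config(seed=17, n_genes=40, n_imprinted=4,
                                  reads_per_gene=120)
        genome = build_genome(cfg)
        batch = simulate_rnaseq(genome, "WT", "polyA+", cfg)
        expected = expected_allele_table(genome)
        fast = count_allelic_rna_batch(batch, cfg.strand_convention, expected)
        idx = SnpIndex(genome.snps)
        records = batch.to_records()
        for gene, f in zip(batch.genes, fast):
            slow = count_allelic_rna(records, gene, idx, cfg.strand_convention,
                                     expected.get(gene.name, "maternal"))
            assert (f.maternal, f.paternal, f.ambiguous, f.uninformative) == \
                (slow.maternal, slow.paternal, slow.ambiguous, slow.uninformative)


class TestThresholdCalls:
    def test_informative_floor_is_strict(self):
        keep = AllelicCount("a", maternal=31, paternal=20)   # 51
        drop = AllelicCount("b", maternal=30, paternal=20)   # 50
        assert filter_informative([keep, drop]) == [keep]

    @pytest.mark.parametrize(
        "maternal,total,category",
        [(67, 100, "strong"), (66, 100, "moderate"), (61, 100, "moderate"),
         (60, 100, "none"), (50, 100, "none")],
    )
    def test_imprinting_categories_strict_thresholds(self, maternal, total, category):
        c = AllelicCount("g", maternal=maternal, paternal=total - maternal)
        assert call_imprinting(c, "maternal").category == category

    def test_strong_call_survives_binomial_noise(self):
        """A 90% skewed gene with >= 200 informative reads is essentially
        always called strong."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = rng.binomial(250, 0.9)
            c = AllelicCount("g", maternal=int(m), paternal=250 - int(m))
            assert call_imprinting(c, "maternal").category == "strong"

    def test_disruption_arithmetic_and_strictness(self):
        wt = AllelicCount("g", maternal=160, paternal=40)    # 0.80
        ko = AllelicCount("g", maternal=138, paternal=62)    # 0.69
        cmp_ = compare_conditions(wt, ko)
        assert cmp_.delta == pytest.approx(0.11)
        assert cmp_.disrupted
        at_thr = AllelicCount("g", maternal=140, paternal=60)  # 0.70, delta 0.10
        assert not compare_conditions(wt, at_thr).disrupted
        assert not compare_conditions(wt, wt).disrupted

    def test_disruption_requires_floor_in_both_conditions(self):
        wt = AllelicCount("g", maternal=40, paternal=10)  # 50 informative
        ko = AllelicCount("g", maternal=60, paternal=140)
        assert not compare_conditions(wt, ko).disrupted


class TestBaseline:
    def test_pure_maternal_panel(self):
        counts = [AllelicCount(f"g{i}", maternal=80) for i in range(10)]
        base = random_gene_baseline(counts)
        assert base.mean == 1.0 and base.sd == 0.0 and base.n_genes == 10

    def test_mean_equals_brute_force_average(self):
        rng = np.random.default_rng(1)
        counts = [AllelicCount(f"g{i}", maternal=int(m), paternal=int(120 - m))
                  for i, m in enumerate(rng.integers(20, 100, size=40))]
        base = random_gene_baseline(counts, floor=50)
        manual = [c.maternal / c.informative for c in counts if c.informative > 50]
        assert base.mean == pytest.approx(np.mean(manual))
        assert base.n_genes == len(manual)
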