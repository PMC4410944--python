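"""Counting, normalization, null construction, enrichment classification and
peak calling, each checked against a naive oracle where one exists."""
import math

import numpy as np
import pytest
from scipy.stats import ks_2samp

from imprintscan.model import GenomeInterval, ReadRecord
from imprintscan.quantify import (
    TrackCounts,
    call_peaks,
    classify_enrichment,
    count_reads_in_intervals,
    count_reads_by_class,
    enriched_flag,
    normalize,
    overlap_enrichment_sets,
    profile_intervals,
    random_fragments,
    repeat_enrichment,
)

from oracles import naive_count, naive_percentile_class


def _random_reads(rng, n, chroms=("chr1", "chr2"), size=100_000, read_len=50):
    return [
        ReadRecord(rng.choice(chroms), s, s + read_len, rng.choice(["+", "-"]))
        for s in rng.integers(0, size - read_len, size=n)
    ]


def _random_intervals(rng, n, chroms=("chr1", "chr2"), size=100_000):
    out = []
    for i in range(n):
        start = int(rng.integers(0, size - 2_000))
        out.append(GenomeInterval(str(rng.choice(chroms)), start,
                                  start + int(rng.integers(50, 2_000)), name=f"iv{i}"))
    return out


class TestNormalize:
    def test_definition_and_scale_invariance(self):
        tc = TrackCounts("t", 1_000_000, {"a": 50})
        assert normalize(tc)["a"] == 50.0
        doubled = TrackCounts("t", 2_000_000, {"a": 100})
        assert normalize(doubled)["a"] == 50.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize(TrackCounts("t", 0, {}))

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(0)
        reads = _random_reads(rng, 5_000)
        intervals = _random_intervals(rng, 40)
        counts = count_reads_in_intervals(reads, intervals)
        rpm = normalize(counts)
        oracle = naive_count(reads, intervals)
        for iv in intervals:
            assert rpm[iv] == pytest.approx(oracle[iv] * 1e6 / len(reads))


class TestCounting:
    def test_single_bp_overlap_counts_half_open_boundary_does_not(self):
        read = [ReadRecord("chr1", 100, 150, "+")]
        hit = GenomeInterval("chr1", 149, 200)
        miss = GenomeInterval("chr1", 150, 200)
        counts = count_reads_in_intervals(read, [hit, miss])
        assert counts.per_interval[hit] == 1
        assert counts.per_interval[miss] == 0

    def test_equals_brute_force_and_order_invariant(self):
        rng = np.random.default_rng(1)
        reads = _random_reads(rng, 10_000)
        intervals = _random_intervals(rng, 100)
        fast = count_reads_in_intervals(reads, intervals).per_interval
        assert fast == naive_count(reads, intervals)
        shuffled_r = list(reads)
        rng.shuffle(shuffled_r)
        shuffled_i = list(intervals)
        rng.shuffle(shuffled_i)
        again = count_reads_in_intervals(shuffled_r, shuffled_i).per_interval
        assert again == fast


class TestRandomFragments:
    def test_lengths_match_template_distribution(self):
        rng = np.random.default_rng(2)
        template = _random_intervals(rng, 600)
        frags = random_fragments({"chr1": 5_000_000}, template, 1_000, seed=7)
        stat = ks_2samp([len(t) for t in template], [len(f) for f in frags])
        assert stat.pvalue > 0.01

    def test_single_fragment_within_bounds_and_deterministic(self):
        template = [GenomeInterval("chrX", 0, 700)]
        a = random_fragments({"chr1": 10_000}, template, 1, seed=3)
        assert a[0].start >= 0 and a[0].end <= 10_000
        b = random_fragments({"chr1": 10_000}, template, 1, seed=3)
        assert a == b

    def test_empty_template_rejected(self):
        with pytest.raises(ValueError):
            random_fragments({"chr1": 1_000}, [], 10, seed=0)


class TestRepeatEnrichment:
    def _tracks(self, chip_counts, input_counts, chip_total=10_000, in_total=10_000):
        return (TrackCounts("chip", chip_total, chip_counts),
                TrackCounts("input", in_total, input_counts))

    def test_low_coverage_excluded_regardless_of_fold(self):
        chip, inp = self._tracks({"sat": 49}, {"sat": 1})
        (r,) = repeat_enrichment(chip, inp)
        assert r.excluded_low_coverage and not r.enriched

    def test_fold_exactly_two_is_not_enriched(self):
        chip, inp = self._tracks({"sat": 100}, {"sat": 50})
        (r,) = repeat_enrichment(chip, inp)
        assert r.fold == pytest.approx(2.0) and not r.enriched

    def test_zero_input_reports_infinity_sentinel(self):
        chip, inp = self._tracks({"sat": 120}, {"sat": 0})
        (r,) = repeat_enrichment(chip, inp)
        assert math.isinf(r.fold) and r.enriched and r.zero_input

    def test_input_vs_input_yields_no_enrichment(self):
        rng = np.random.default_rng(3)
        counts = {f"c{i}": int(rng.integers(60, 500)) for i in range(8)}
        chip, inp = self._tracks(dict(counts), dict(counts))
        assert all(r.fold == pytest.approx(1.0) and not r.enriched
                   for r in repeat_enrichment(chip, inp))

    def test_planted_pericentric_enrichment_called(self, demo_pipeline):
        import csv

        with open(demo_pipeline.reports["repeats"]) as fh:
            rows = {r["repeat_class"]: r for r in csv.DictReader(fh, delimiter="\t")}
        assert rows["pericentric"]["enriched"] == "1"
        assert rows["line"]["enriched"] == "0"


class TestPercentileClasses:
    def test_boundary_trio(self):
        baseline = list(range(1, 101))
        assert classify_enrichment(np.median(baseline), baseline) == "mid"
        assert classify_enrichment(1_000, baseline) == "high"
        assert classify_enrichment(25, baseline) == "mid"  # strict <
        assert classify_enrichment(24, baseline) == "low"
        assert classify_enrichment(76, baseline) == "high"

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            baseline = rng.normal(size=int(rng.integers(4, 60))).tolist()
            value = float(rng.normal())
            assert classify_enrichment(value, baseline) == \
                naive_percentile_class(value, baseline)

    def test_baseline_against_itself_partitions_quarters(self):
        rng = np.random.default_rng(5)
        baseline = rng.normal(size=1_000).tolist()
        classes = [classify_enrichment(v, baseline) for v in baseline]
        for cls, frac in (("low", 0.25), ("mid", 0.5), ("high", 0.25)):
            assert abs(classes.count(cls) / len(classes) - frac) < 0.02

    def test_enriched_flag_is_strict_above_p75(self):
        null = list(range(1, 101))
        assert not enriched_flag(75, null)
        assert enriched_flag(75.5, null)
        assert not enriched_flag(10, null)


class TestOverlapSets:
    def test_all_enriched_collapses_to_triple_cell(self):
        rng = np.random.default_rng(6)
        ivs = _random_intervals(rng, 5, chroms=("chr1",))
        marks = ["A", "B", "C"]
        profiles = profile_intervals(ivs, {}, None, None)
        for p in profiles:
            p.enriched = {m: True for m in marks}
        _, cells = overlap_enrichment_sets(profiles, marks)
        assert cells == {frozenset(marks): 5}

    def test_disjoint_marks_have_no_triple_overlap_and_cells_sum(self):
        rng = np.random.default_rng(7)
        ivs = _random_intervals(rng, 6, chroms=("chr1",))
        marks = ["A", "B", "C"]
        profiles = profile_intervals(ivs, {}, None, None)
        for i, p in enumerate(profiles):
            p.enriched = {m: (j == i % 3) for j, m in enumerate(marks)}
        membership, cells = overlap_enrichment_sets(profiles, marks)
        assert frozenset(marks) not in cells
        assert sum(cells.values()) == sum(any(f) for f in membership.values())


class TestPeakCalling:
    @staticmethod
    def _uniform(chrom, size, step, read_len=50, track=""):
        return [ReadRecord(chrom, s, s + read_len, "+", track=track)
                for s in range(0, size - read_len, step)]

    def test_planted_region_recovered(self):
        size = 100_000
        chip = self._uniform("chr1", size, 40)
        chip += [ReadRecord("chr1", s, s + 50, "+") for s in range(50_000, 52_000, 5)]
        inp = self._uniform("chr1", size, 40)
        peaks = call_peaks(chip, inp, {"chr1": size}, fold_threshold=3.0)
        assert len(peaks) == 1
        ov = min(peaks[0].end, 52_000) - max(peaks[0].start, 50_000)
        assert ov / 2_000 >= 0.8

    def test_identical_tracks_produce_no_peaks(self):
        reads = self._uniform("chr1", 50_000, 20)
        assert call_peaks(reads, list(reads), {"chr1": 50_000},
                          fold_threshold=2.0) == []

    def test_separated_regions_stay_separate_peaks(self):
        size = 60_000
        chip = self._uniform("chr1", size, 40)
        for region in (10_000, 40_000):
            chip += [ReadRecord("chr1", s, s + 50, "+")
                     for s in range(region, region + 1_500, 5)]
        inp = self._uniform("chr1", size, 40)
        peaks = call_peaks(chip, inp, {"chr1": size}, fold_threshold=3.0,
                           merge_gap=500)
        assert len(peaks) == 2


def test_count_by_class_aggregates_instances():
    reads = [ReadRecord("chr1", 100, 150, "+"), ReadRecord("chr1", 500, 550, "+"),
             ReadRecord("chr1", 900, 950, "+")]
    repeats = [GenomeInterval("chr1", 90, 200, "r1", "ervk"),
               GenomeInterval("chr1", 480, 600, "r2", "ervk"),
               GenomeInterval("chr1", 880, 1_000, "r3", "line")]
    by_class = count_reads_by_class(reads, repeats).per_interval
    assert by_class == {"ervk": 2, "line": 1}
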