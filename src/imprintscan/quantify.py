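"""Read counting, normalization and enrichment scoring.

Counts are normalized to reads per million mapped reads (RPM). Interval
enrichment is judged against a null of random genomic fragments matched to
the template intervals' length distribution: an interval is "enriched" for a
mark iff its RPM exceeds the null's 75th percentile. Three-way low/mid/high
classes use the 25th/75th percentiles of a baseline distribution with strict
comparisons on both sides.

Repeat-class enrichment follows the published rule: classes with fewer than
50 raw mapped ChIP reads are excluded; the rest are enriched iff
ChIP RPM / input RPM exceeds 2 strictly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Hashable, Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .model import GenomeInterval, ReadRecord

# percentiles via the floor-type order statistic so that e.g. P25 of 1..100
# is exactly 25 and strict "<"/">" comparisons behave as printed
PERCENTILE_METHOD = "lower"


@dataclass
class TrackCounts:
    """Raw per-interval (or per-class) read tallies for one library."""

    track: str
    total_mapped: int
    per_interval: dict[Hashable, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_mapped < 0 or any(v < 0 for v in self.per_interval.values()):
            raise ValueError("counts must be non-negative")
        if any(v > self.total_mapped for v in self.per_interval.values()):
            raise ValueError("per-interval count exceeds total mapped reads")


def normalize(counts: TrackCounts) -> dict[Hashable, float]:
    """Reads-per-million of total mapped reads, per interval."""
    if counts.total_mapped <= 0:
        raise ValueError(f"track {counts.track}: zero total mapped reads")
    scale = 1e6 / counts.total_mapped
    return {k: v * scale for k, v in counts.per_interval.items()}


def count_reads_in_intervals(
    reads: Iterable[ReadRecord],
    intervals: Sequence[GenomeInterval],
    track: str = "",
) -> TrackCounts:
    """A read counts toward every interval its span overlaps by >= 1 bp."""
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    tallies: dict[Hashable, int] = {iv: 0 for iv in intervals}
    total = 0
    for read in reads:
        total += 1
        tree = trees.get(read.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(read.start, read.end):
            tallies[hit.data] += 1
        if not track:
            track = read.track
    return TrackCounts(track=track, total_mapped=total, per_interval=tallies)


def count_reads_by_class(
    reads: Iterable[ReadRecord],
    intervals: Sequence[GenomeInterval],
    track: str = "",
) -> TrackCounts:
    """Tally reads per interval ``kind`` (repeat class); every overlapped
    instance counts once, so a read spanning two instances of the same class
    contributes twice — matching multi-placement repeat quantitation."""
    per_iv = count_reads_in_intervals(reads, intervals, track=track)
    by_class: dict[Hashable, int] = {}
    for iv, n in per_iv.per_interval.items():
        by_class[iv.kind] = by_class.get(iv.kind, 0) + n
    return TrackCounts(track=per_iv.track, total_mapped=per_iv.total_mapped,
                       per_interval=by_class)


def random_fragments(
    genome_sizes: dict[str, int],
    template_intervals: Sequence[GenomeInterval],
    n: int,
    seed: int,
) -> list[GenomeInterval]:
    """``n`` fragments with lengths resampled from the template length
    distribution, placed uniformly on the genome."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not template_intervals:
        raise ValueError("template interval set is empty")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(iv) for iv in template_intervals], dtype=np.int64)
    chroms = list(genome_sizes)
    sizes = np.array([genome_sizes[c] for c in chroms], dtype=np.int64)
    if lengths.max() > sizes.max():
        raise ValueError("template fragment longer than every chromosome")
    out: list[GenomeInterval] = []
    while len(out) < n:
        want = n - len(out)
        ls = rng.choice(lengths, size=want)
        ci = rng.choice(len(chroms), size=want, p=sizes / sizes.sum())
        fit = ls <= sizes[ci]
        starts = (rng.random(want) * (sizes[ci] - ls + 1)).astype(np.int64)
        for k in np.flatnonzero(fit):
            out.append(GenomeInterval(chroms[ci[k]], int(starts[k]),
                                      int(starts[k] + ls[k]),
                                      name=f"rand{len(out)}", kind="random"))
    return out


@dataclass
class RepeatEnrichment:
    repeat_class: str
    chip_raw: int
    chip_norm: float
    input_norm: float
    fold: float
    enriched: bool
    excluded_low_coverage: bool
    zero_input: bool = False


def repeat_enrichment(
    chip: TrackCounts,
    input_: TrackCounts,
    min_reads: int = 50,
    fold_threshold: float = 2.0,
) -> list[RepeatEnrichment]:
    """Per-class fold over input with the low-coverage exclusion.

    Classes with fewer than ``min_reads`` raw ChIP reads are excluded
    regardless of fold; zero input RPM with ChIP reads present yields an
    +inf fold, reported enriched and flagged.
    """
    if set(chip.per_interval) != set(input_.per_interval):
        raise ValueError("ChIP and input are not quantified over the same classes")
    chip_rpm = normalize(chip)
    input_rpm = normalize(input_)
    out = []
    for cls in chip.per_interval:
        raw = chip.per_interval[cls]
        raw_in = input_.per_interval[cls]
        excluded = raw < min_reads
        c, i = chip_rpm[cls], input_rpm[cls]
        zero_input = raw_in == 0 and raw > 0
        if zero_input:
            fold = math.inf
            above = True
        elif raw_in == 0:
            fold = 0.0
            above = False
        else:
            # exact rational fold so the strict ">2" boundary has no
            # floating-point artifacts
            exact = Fraction(raw * input_.total_mapped, raw_in * chip.total_mapped)
            fold = float(exact)
            above = exact > Fraction(str(fold_threshold))
        out.append(RepeatEnrichment(
            repeat_class=str(cls), chip_raw=raw, chip_norm=c, input_norm=i,
            fold=fold, enriched=(not excluded) and above,
            excluded_low_coverage=excluded, zero_input=zero_input,
        ))
    return out


def classify_enrichment(value: float, baseline_values: Sequence[float]) -> str:
    """Three-way class against a baseline: low (< P25), high (> P75), else mid."""
    if len(baseline_values) == 0:
        raise ValueError("baseline is empty")
    p25, p75 = np.percentile(baseline_values, [25, 75], method=PERCENTILE_METHOD)
    if value < p25:
        return "low"
    if value > p75:
        return "high"
    return "mid"


def enriched_flag(value: float, null_values: Sequence[float]) -> bool:
    """True iff value strictly exceeds the null's 75th percentile."""
    if len(null_values) == 0:
        raise ValueError("null distribution is empty")
    return bool(value > np.percentile(null_values, 75, method=PERCENTILE_METHOD))


@dataclass
class IntervalProfile:
    """Per-interval normalized counts with enrichment flags and classes."""

    interval: GenomeInterval
    normalized: dict[str, float] = field(default_factory=dict)
    enrichment_class: dict[str, str] = field(default_factory=dict)
    enriched: dict[str, bool] = field(default_factory=dict)


def profile_intervals(
    intervals: Sequence[GenomeInterval],
    tracks: dict[str, Sequence[ReadRecord]],
    null_intervals: Sequence[GenomeInterval] | None = None,
    baseline_intervals: Sequence[GenomeInterval] | None = None,
) -> list[IntervalProfile]:
    """Quantify each track over ``intervals``; flag enrichment against the
    random-fragment null and assign low/mid/high against the baseline set
    (e.g. all genomic CGIs) when supplied."""
    profiles = [IntervalProfile(iv) for iv in intervals]
    by_iv = {iv: p for iv, p in zip(intervals, profiles)}
    for mark, reads in tracks.items():
        counts = count_reads_in_intervals(reads, list(intervals), track=mark)
        rpm = normalize(counts)
        null_rpm = base_rpm = None
        if null_intervals:
            null_rpm = list(normalize(
                count_reads_in_intervals(reads, list(null_intervals), track=mark)
            ).values())
        if baseline_intervals:
            base_rpm = list(normalize(
                count_reads_in_intervals(reads, list(baseline_intervals), track=mark)
            ).values())
        for iv in intervals:
            p = by_iv[iv]
            p.normalized[mark] = rpm[iv]
            if null_rpm is not None:
                p.enriched[mark] = enriched_flag(rpm[iv], null_rpm)
            if base_rpm is not None:
                p.enrichment_class[mark] = classify_enrichment(rpm[iv], base_rpm)
    return profiles


def overlap_enrichment_sets(
    profiles: Sequence[IntervalProfile], marks: Sequence[str]
):
    """Per-interval enrichment membership plus disjoint Venn-cell counts.

    Returns ``(membership, cells)``: membership maps interval -> tuple of
    flags in mark order; cells maps each non-empty frozenset of marks to the
    number of intervals enriched for exactly that combination.
    """
    membership: dict[GenomeInterval, tuple[bool, ...]] = {}
    cells: dict[frozenset, int] = {}
    for p in profiles:
        flags = tuple(bool(p.enriched.get(m, False)) for m in marks)
        membership[p.interval] = flags
        key = frozenset(m for m, f in zip(marks, flags) if f)
        if key:
            cells[key] = cells.get(key, 0) + 1
    return membership, cells


def call_peaks(
    chip_reads: Sequence[ReadRecord],
    input_reads: Sequence[ReadRecord],
    chrom_sizes: dict[str, int],
    window_bp: int = 1_000,
    fold_threshold: float = 2.0,
    merge_gap: int = 500,
    min_reads: int = 10,
) -> list[GenomeInterval]:
    """Simple window/fold/merge peak caller.

    Tiles each chromosome; keeps windows whose ChIP RPM strictly exceeds
    ``fold_threshold`` x input RPM with at least ``min_reads`` raw ChIP
    reads; merges kept windows separated by <= ``merge_gap``. A read
    contributes to every window it overlaps.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    total_chip = len(chip_reads)
    total_input = len(input_reads)
    if total_chip == 0 or total_input == 0:
        raise ValueError("both ChIP and input tracks must contain reads")

    def window_counts(reads: Sequence[ReadRecord], chrom: str, nwin: int) -> np.ndarray:
        w = np.zeros(nwin, dtype=np.int64)
        for r in reads:
            if r.chrom != chrom:
                continue
            first = r.start // window_bp
            last = (r.end - 1) // window_bp
            w[first: last + 1] += 1
        return w

    peaks: list[GenomeInterval] = []
    for chrom, size in chrom_sizes.items():
        nwin = (size + window_bp - 1) // window_bp
        cw = window_counts(chip_reads, chrom, nwin)
        iw = window_counts(input_reads, chrom, nwin)
        keep = (cw >= min_reads) & (
            cw * (1e6 / total_chip) > fold_threshold * iw * (1e6 / total_input)
        )
        idx = np.flatnonzero(keep)
        if not len(idx):
            continue
        run_start = int(idx[0])
        prev = int(idx[0])
        runs = []
        for i in idx[1:]:
            if (int(i) - prev - 1) * window_bp > merge_gap:
                runs.append((run_start, prev))
                run_start = int(i)
            prev = int(i)
        runs.append((run_start, prev))
        for a, b in runs:
            peaks.append(GenomeInterval(chrom, a * window_bp,
                                        min((b + 1) * window_bp, size),
                                        name=f"{chrom}_peak{a}", kind="peak"))
    return peaks
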