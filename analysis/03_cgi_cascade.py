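#!/usr/bin/env python
"""Step 3 — sequential CGI filtering.

Classifies every CGI by position (promoter/intragenic/intergenic), then
applies the filter cascade — DNA methylation, H3K9me3+H4K20me3, H3.3,
active transcription — and reports how the ATRX-bound and imprinted
fractions rise as the survivor set shrinks.
"""
import argparse
from pathlib import Path

from imprintscan.cgi_annotate import annotate_cgis, classify_cgi_position, run_filter_cascade
from imprintscan.io import read_fixtures
from imprintscan.model import GenomeInterval
from imprintscan.pipeline import CHIP_MARKS, _write_tsv
from imprintscan.quantify import (
    call_peaks,
    count_reads_in_intervals,
    profile_intervals,
    random_fragments,
)

parser = argparse.ArgumentParser()
parser.add_argument("--fixtures", type=Path, default=Path("results/fixtures"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

genome, reads = read_fixtures(args.fixtures)
ann = genome.annotations
args.out.mkdir(parents=True, exist_ok=True)

classes = [classify_cgi_position(c, ann.genes) for c in ann.cgis]
for cls in ("promoter", "intragenic", "intergenic"):
    print(f"{cls} CGIs: {classes.count(cls)}")

peaks = call_peaks(reads["ATRX"], reads["input"], genome.chrom_sizes)
null = random_fragments(genome.chrom_sizes, ann.cgis, 500, seed=17)
profiles = profile_intervals(ann.cgis, {m: reads[m] for m in CHIP_MARKS},
                             null, ann.cgis)
rna = next(v for k, v in reads.items() if k.startswith("RNA_WT"))
gene_ivs = [GenomeInterval(g.chrom, g.start, g.end, g.name) for g in ann.genes]
counts = count_reads_in_intervals(rna, gene_ivs, track="rna")
transcribed = {
    iv.name for iv, n in counts.per_interval.items()
    if n / ((iv.end - iv.start) / 1e3) / (counts.total_mapped / 1e6) > 1.0
}
annos = annotate_cgis(ann.cgis, ann.genes, peaks, ann.dmrs, profiles, transcribed)
cascade = run_filter_cascade(annos)
_write_tsv(args.out / "cgi_cascade.tsv",
           ["stage", "surviving", "fraction_atrx_bound", "fraction_imprinted"],
           [[s.name, s.surviving, s.fraction_atrx_bound, s.fraction_imprinted]
            for s in cascade.stages])
for s in cascade.stages:
    frac = "NA" if s.fraction_atrx_bound is None else f"{s.fraction_atrx_bound:.0%}"
    print(f"after {s.name:<12} {s.surviving:>3} CGIs remain, {frac} ATRX-bound")
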