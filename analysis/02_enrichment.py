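#!/usr/bin/env python
"""Step 2 — enrichment landscape.

From the simulated fixtures: calls ATRX peaks against input with the
window/fold caller, scores repeat-class enrichment (RPM fold over input with
the <50-read exclusion), and profiles every CGI for each mark against a
random-fragment null, reporting the heterochromatin/H3.3 overlap structure
under ATRX peaks.
"""
import argparse
from pathlib import Path

from imprintscan.io import read_fixtures
from imprintscan.pipeline import CHIP_MARKS, _write_tsv
from imprintscan.quantify import (
    call_peaks,
    count_reads_by_class,
    overlap_enrichment_sets,
    profile_intervals,
    random_fragments,
    repeat_enrichment,
)

parser = argparse.ArgumentParser()
parser.add_argument("--fixtures", type=Path, default=Path("results/fixtures"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

genome, reads = read_fixtures(args.fixtures)
ann = genome.annotations
args.out.mkdir(parents=True, exist_ok=True)

peaks = call_peaks(reads["ATRX"], reads["input"], genome.chrom_sizes)
with open(args.out / "peaks.bed", "w") as fh:
    for p in peaks:
        fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\n")
print(f"called {len(peaks)} ATRX peaks "
      f"(truth: {len(ann.dmrs)} DMRs + enriched repeat blocks)")

chip_cls = count_reads_by_class(reads["ATRX"], ann.repeats, track="ATRX")
in_cls = count_reads_by_class(reads["input"], ann.repeats, track="input")
rep = sorted(repeat_enrichment(chip_cls, in_cls), key=lambda r: r.repeat_class)
_write_tsv(args.out / "repeat_enrichment.tsv",
           ["repeat_class", "chip_raw", "chip_rpm", "input_rpm", "fold",
            "enriched", "excluded_low_coverage"],
           [[r.repeat_class, r.chip_raw, r.chip_norm, r.input_norm, r.fold,
             r.enriched, r.excluded_low_coverage] for r in rep])
enriched = [r.repeat_class for r in rep if r.enriched]
print(f"repeat classes enriched >2-fold over input: {', '.join(enriched)}")

null = random_fragments(genome.chrom_sizes, ann.cgis, 500, seed=17)
chip = {m: reads[m] for m in CHIP_MARKS}
profiles = profile_intervals(ann.cgis, chip, null, ann.cgis)
marks = ["H3K9me3", "H4K20me3", "H3.3"]
_, cells = overlap_enrichment_sets(profiles, marks)
triple = cells.get(frozenset(marks), 0)
print(f"CGIs enriched for all of H3K9me3/H4K20me3/H3.3 vs the random-fragment "
      f"null: {triple} of {len(ann.cgis)}")
_write_tsv(args.out / "cgi_profiles.tsv",
           ["cgi", "kind", *[f"{m}_rpm" for m in CHIP_MARKS],
            *[f"{m}_enriched" for m in marks]],
           [[p.interval.name, p.interval.kind,
             *[p.normalized[m] for m in CHIP_MARKS],
             *[p.enriched[m] for m in marks]] for p in profiles])
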