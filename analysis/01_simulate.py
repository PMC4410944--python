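#!/usr/bin/env python
"""Step 1 — simulate the study system.

Builds the demo diploid genome (two strains' haplotypes, 18 imprinted loci
with methylated intragenic CGIs/DMRs, repeats, balanced background genes),
draws the six ChIP tracks and the WT/KO strand-specific RNA libraries, and
writes the fixture set (FASTA/VCF/BED/SAM + truth tables) that the later
steps read.
"""
import argparse
from pathlib import Path

from imprintscan.config import demo_config
from imprintscan.io import write_fixtures
from imprintscan.pipeline import CHIP_MARKS
from imprintscan.synthetic_data import build_genome, simulate_chip_track, simulate_rnaseq

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/fixtures"))
args = parser.parse_args()

cfg = demo_config(seed=args.seed)
genome = build_genome(cfg)
ann = genome.annotations
print(f"genome: {len(genome.chrom_names)} chromosomes, "
      f"{sum(genome.chrom_sizes.values()):,} bp, {len(genome.snps)} SNPs")
print(f"annotations: {len(ann.genes)} genes ({len(ann.dmrs)} imprinted), "
      f"{len(ann.cgis)} CGIs, {len(ann.repeats)} repeat intervals")

reads = {m: simulate_chip_track(genome, m, cfg) for m in CHIP_MARKS}
for cond in ("WT", "KO"):
    batch = simulate_rnaseq(genome, cond, "polyA+", cfg)
    reads[batch.track] = batch.to_records()
paths = write_fixtures(genome, reads, args.out, config=cfg)
print(f"wrote {len(paths)} fixture files to {args.out}")
for track, recs in reads.items():
    print(f"  {track}: {len(recs):,} reads")
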