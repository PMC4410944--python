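#!/usr/bin/env python
"""Step 5 — in-silico RFLP validation.

For the first DMRs, designs an allelic-discrimination assay (a synthetic
enzyme whose site spans a DMR SNP on one allele only), converts the
H3K9me3 ChIP and input read skews into gel lanes, and quantifies allelic
enrichment relative to input — the orthogonal readout of the skews measured
in step 4.
"""
import argparse
from pathlib import Path

from imprintscan.allelic import count_allelic_chip
from imprintscan.digest import AssayDesignError, quantify_allelic, simulate_bands
from imprintscan.io import read_fixtures
from imprintscan.pipeline import _write_tsv, design_dmr_assay
from imprintscan.snps import SnpIndex

parser = argparse.ArgumentParser()
parser.add_argument("--fixtures", type=Path, default=Path("results/fixtures"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--mark", default="H3K9me3")
args = parser.parse_args()

genome, reads = read_fixtures(args.fixtures)
snps = SnpIndex(genome.snps)
args.out.mkdir(parents=True, exist_ok=True)

rows = []
for dmr in genome.annotations.dmrs:
    try:
        assay = design_dmr_assay(genome, dmr, snps)
    except AssayDesignError:
        print(f"{dmr.name}: no discriminating SNP/enzyme pair")
        continue
    chip = count_allelic_chip(reads[args.mark], dmr, snps)
    inp = count_allelic_chip(reads["input"], dmr, snps)
    f_chip = chip.skew_toward(assay.cutting_allele)
    f_inp = inp.skew_toward(assay.cutting_allele)
    if f_chip is None or not f_inp:
        continue
    enr = quantify_allelic(assay, simulate_bands(assay, f_chip),
                           simulate_bands(assay, f_inp))
    rows.append([dmr.name, assay.snp.pos, assay.enzyme_site, assay.cutting_allele,
                 dmr.methylated_parent, f_chip, f_inp, enr])
    direction = "enriched" if enr > 1 else "depleted"
    print(f"{dmr.name}: cuts {assay.cutting_allele} "
          f"(methylated: {dmr.methylated_parent}); {args.mark} {direction} "
          f"{enr:.2f}x vs input")
_write_tsv(args.out / "digest.tsv",
           ["dmr", "snp_pos", "enzyme_site", "cutting_allele",
            "methylated_parent", "chip_cut_fraction", "input_cut_fraction",
            "enrichment_vs_input"], rows)
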