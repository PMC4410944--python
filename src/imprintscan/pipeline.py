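"""End-to-end demo pipeline: simulate -> quantify -> CGI cascade -> allelic
WT/KO comparison -> in-silico digest, with deterministic TSV/BED reports.

Every report is re-derivable from the seed alone; re-running with the same
config reproduces byte-identical files.
"""
from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .allelic import (
    AllelicCount,
    call_imprinting,
    compare_conditions,
    count_allelic_chip,
    count_allelic_rna_batch,
    random_gene_baseline,
)
from .cgi_annotate import annotate_cgis, run_filter_cascade
from .config import PipelineConfig
from .digest import (
    AssayDesignError,
    DigestAssay,
    design_assay,
    quantify_allelic,
    simulate_bands,
)
from .model import DiploidGenome, DmrInterval, MATERNAL, PATERNAL
from .quantify import (
    call_peaks,
    count_reads_by_class,
    profile_intervals,
    random_fragments,
    repeat_enrichment,
)
from .snps import SnpIndex
from .synthetic_data import (
    build_genome,
    expected_allele_table,
    simulate_chip_track,
    simulate_rnaseq,
)

CHIP_MARKS = ("ATRX", "H3.3", "H3K9me3", "H4K20me3", "H3K4me3", "input")
ALLELIC_MARKS = ("ATRX", "H3.3", "H3K9me3", "H3K4me3")
UNDEF = "NA"


def _fmt(x) -> str:
    if x is None:
        return UNDEF
    if isinstance(x, bool):
        return str(int(x))
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


@dataclass
class PipelineResult:
    out_dir: Path
    reports: dict[str, Path] = field(default_factory=dict)
    genome: DiploidGenome | None = None
    disrupted_genes: list[str] = field(default_factory=list)
    baseline_mean: float | None = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    thr = config.thresholds
    sim = config.simulation
    sim.seed = config.seed
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(out_dir=out)

    # --- simulate ---------------------------------------------------------
    genome = build_genome(sim)
    result.genome = genome
    ann = genome.annotations
    chip = {m: simulate_chip_track(genome, m, sim) for m in CHIP_MARKS}
    rna = {cond: simulate_rnaseq(genome, cond, "polyA+", sim) for cond in ("WT", "KO")}
    snp_index = SnpIndex(genome.snps)

    # --- peaks ------------------------------------------------------------
    peaks = call_peaks(chip["ATRX"], chip["input"], genome.chrom_sizes,
                       thr.peak_window_bp, thr.peak_fold, thr.peak_merge_gap,
                       thr.peak_min_reads)
    peaks_path = out / "peaks.bed"
    with open(peaks_path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\n")
    result.reports["peaks"] = peaks_path

    # --- repeat-class enrichment ------------------------------------------
    chip_cls = count_reads_by_class(chip["ATRX"], ann.repeats, track="ATRX")
    input_cls = count_reads_by_class(chip["input"], ann.repeats, track="input")
    rep = repeat_enrichment(chip_cls, input_cls, thr.repeat_min_reads, thr.repeat_fold)
    rep_path = out / "repeat_enrichment.tsv"
    _write_tsv(rep_path,
               ["repeat_class", "chip_raw", "chip_rpm", "input_rpm", "fold",
                "enriched", "excluded_low_coverage"],
               [[r.repeat_class, r.chip_raw, r.chip_norm, r.input_norm,
                 "inf" if r.fold == float("inf") else r.fold,
                 r.enriched, r.excluded_low_coverage]
                for r in sorted(rep, key=lambda r: r.repeat_class)])
    result.reports["repeats"] = rep_path

    # --- CGI profiles and filter cascade ----------------------------------
    null = random_fragments(genome.chrom_sizes, ann.cgis, n=500,
                            seed=(config.seed * 1_000_003 + 17) % (2**31))
    profiles = profile_intervals(ann.cgis, chip, null_intervals=null,
                                 baseline_intervals=ann.cgis)

    wt_counts = count_allelic_rna_batch(rna["WT"], sim.strand_convention,
                                        expected_allele_table(genome))
    total_rna = len(rna["WT"])
    transcribed = set()
    for gene, c in zip(rna["WT"].genes, wt_counts):
        reads_in_gene = c.maternal + c.paternal + c.ambiguous + c.uninformative
        rpkm = reads_in_gene / ((gene.end - gene.start) / 1e3) / (total_rna / 1e6)
        if rpkm > thr.transcribed_min_rpkm:
            transcribed.add(gene.name)

    annos = annotate_cgis(ann.cgis, ann.genes, peaks, ann.dmrs, profiles,
                          transcribed, thr.promoter_window_bp)
    cascade = run_filter_cascade(annos)
    cascade_path = out / "cgi_cascade.tsv"
    _write_tsv(cascade_path,
               ["stage", "surviving", "fraction_atrx_bound", "fraction_imprinted"],
               [[s.name, s.surviving, s.fraction_atrx_bound, s.fraction_imprinted]
                for s in cascade.stages])
    result.reports["cgi_cascade"] = cascade_path

    # --- allelic ChIP at DMRs ---------------------------------------------
    chip_rows = []
    dmr_chip_counts: dict[tuple[str, str], AllelicCount] = {}
    for dmr in ann.dmrs:
        for mark in ALLELIC_MARKS:
            c = count_allelic_chip(chip[mark], dmr, snp_index,
                                   expected_allele=dmr.methylated_parent)
            dmr_chip_counts[(dmr.name, mark)] = c
            chip_rows.append([dmr.name, mark, dmr.methylated_parent, c.maternal,
                              c.paternal, c.ambiguous, c.informative,
                              c.skew_expected])
    chip_path = out / "allelic_chip.tsv"
    _write_tsv(chip_path,
               ["dmr", "mark", "methylated_parent", "maternal", "paternal",
                "ambiguous", "informative", "skew_toward_methylated"],
               chip_rows)
    result.reports["allelic_chip"] = chip_path
    result.dmr_chip_counts = dmr_chip_counts  # type: ignore[attr-defined]

    # --- allelic RNA: imprinting calls and WT/KO comparison ---------------
    expected = expected_allele_table(genome)
    ko_counts = count_allelic_rna_batch(rna["KO"], sim.strand_convention, expected)
    rna_rows = []
    for gene, wt_c, ko_c in zip(rna["WT"].genes, wt_counts, ko_counts):
        imprinted = gene.name in expected
        call = call_imprinting(wt_c, fraction="polyA+", strong=thr.skew_strong,
                               moderate=thr.skew_moderate)
        cmp_ = compare_conditions(wt_c, ko_c, thr.delta_disrupted,
                                  thr.informative_floor)
        if cmp_.disrupted:
            result.disrupted_genes.append(gene.name)
        rna_rows.append([gene.name, int(imprinted), wt_c.expected_allele,
                         wt_c.informative, ko_c.informative, call.skew,
                         call.category, cmp_.skew_ko, cmp_.delta, cmp_.disrupted])
    baseline = random_gene_baseline(
        [c for g, c in zip(rna["WT"].genes, wt_counts) if g.name not in expected],
        parent=MATERNAL, floor=thr.informative_floor)
    result.baseline_mean = baseline.mean
    rna_path = out / "allelic_rna.tsv"
    _write_tsv(rna_path,
               ["gene", "imprinted", "expected_allele", "informative_wt",
                "informative_ko", "skew_wt", "category_wt", "skew_ko", "delta",
                "disrupted"],
               rna_rows)
    result.reports["allelic_rna"] = rna_path

    # --- in-silico RFLP digest --------------------------------------------
    digest_rows = []
    for dmr in ann.dmrs[:4]:
        try:
            assay = design_dmr_assay(genome, dmr, snp_index)
        except AssayDesignError:
            continue
        input_c = count_allelic_chip(chip["input"], dmr, snp_index)
        chip_c = dmr_chip_counts[(dmr.name, "H3K9me3")]
        cut = assay.cutting_allele
        f_chip = chip_c.skew_toward(cut)
        f_input = input_c.skew_toward(cut)
        if f_chip is None or not f_input:
            continue
        lane = simulate_bands(assay, f_chip, lane=f"H3K9me3_{dmr.name}")
        input_lane = simulate_bands(assay, f_input, lane=f"input_{dmr.name}")
        enr = quantify_allelic(assay, lane, input_lane)
        digest_rows.append([dmr.name, assay.snp.pos, assay.enzyme_site, cut,
                            len(assay.amplicon_maternal),
                            ",".join(map(str, assay.fragments[cut])),
                            f_chip, f_input, enr])
    digest_path = out / "digest.tsv"
    _write_tsv(digest_path,
               ["dmr", "snp_pos", "enzyme_site", "cutting_allele", "amplicon_bp",
                "cut_fragments", "chip_cut_fraction", "input_cut_fraction",
                "enrichment_vs_input"],
               digest_rows)
    result.reports["digest"] = digest_path

    # --- run log -----------------------------------------------------------
    log = {
        "seed": config.seed,
        "thresholds": asdict(thr),
        "versions": {"imprintscan": __version__, "numpy": np.__version__,
                     "python": platform.python_version()},
        "reports": {k: str(v.name) for k, v in result.reports.items()},
        "n_disrupted": len(result.disrupted_genes),
        "baseline_mean_skew": result.baseline_mean,
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    result.reports["run_log"] = log_path
    return result


def design_dmr_assay(
    genome: DiploidGenome,
    dmr: DmrInterval,
    snp_index: SnpIndex,
    primer_len: int = 20,
    flank: int = 150,
) -> DigestAssay:
    """Design a synthetic discriminating assay at the first workable SNP of a
    DMR: the enzyme's recognition site is the maternal hexamer spanning the
    SNP, primers are SNP-free 20-mers in the flanks."""
    pos, _, _ = snp_index.in_span(dmr.chrom, dmr.start, dmr.end)
    mat = genome.maternal_seq[dmr.chrom]

    def snp_free(start: int, end: int) -> bool:
        p, _, _ = snp_index.in_span(dmr.chrom, start, end)
        return len(p) == 0

    from .digest import reverse_complement
    from .model import SnpRecord

    for p in pos:
        p = int(p)
        site = mat[p - 2: p + 4]
        if len(site) < 6:
            continue
        f_start = next((s for s in range(p - flank, p - flank + 60)
                        if s >= 0 and snp_free(s, s + primer_len)), None)
        r_end = next((e for e in range(p + flank, p + flank - 60, -1)
                      if e + primer_len <= len(mat) and snp_free(e, e + primer_len)), None)
        if f_start is None or r_end is None:
            continue
        fwd = mat[f_start: f_start + primer_len]
        rev = reverse_complement(mat[r_end: r_end + primer_len])
        snp = next(s for s in genome.snps if s.chrom == dmr.chrom and s.pos == p)
        try:
            assay = design_assay(genome, snp, (fwd, rev), site)
        except AssayDesignError:
            continue
        if assay.usable:
            return assay
    raise AssayDesignError(f"no discriminating SNP/enzyme found in {dmr.name}")
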