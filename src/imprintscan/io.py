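"""Fixture serialization: FASTA + VCF + BED + SAM + truth TSVs.

Coordinates are converted to 1-based only at the VCF/SAM boundary. The VCF
encodes the maternal allele as REF and the paternal allele as ALT, with a
single phased sample ``F1`` carrying ``0|1`` (maternal|paternal). SAM reads
carry the chosen-haplotype sequence, so SNP bases encode parental origin,
plus an ``XH`` truth tag (0 maternal / 1 paternal).
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import SimulationConfig
from .model import (
    CgiInterval,
    DiploidGenome,
    DmrInterval,
    GeneModel,
    GenomeAnnotation,
    GenomeInterval,
    ReadRecord,
    SnpRecord,
)
from .snps import SnpIndex


def _track_filename(track: str) -> str:
    safe = track.replace("polyA+", "polyAplus").replace("polyA-", "polyAminus")
    return f"reads_{safe}.sam"


def write_fixtures(
    genome: DiploidGenome,
    reads: dict[str, Sequence[ReadRecord]],
    out_dir: str | Path,
    config: SimulationConfig | None = None,
) -> dict[str, Path]:
    """Write the full fixture set; round-trips losslessly through
    :func:`read_fixtures`. When ``config`` is given, per-mark ground-truth
    enriched intervals are written as ``truth_peaks.bed``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for hap, attr in (("maternal", genome.maternal_seq), ("paternal", genome.paternal_seq)):
        path = out / f"{hap}.fa"
        SeqIO.write(
            [SeqRecord(Seq(attr[c]), id=c, description="") for c in genome.chrom_names],
            str(path), "fasta",
        )
        paths[f"fasta_{hap}"] = path

    paths["vcf"] = _write_vcf(genome, out / "snps.vcf")
    paths["genes_bed"] = _write_genes_bed(genome.annotations.genes, out / "genes.bed")
    paths["cgis_bed"] = _write_cgis_bed(genome.annotations.cgis, out / "cgis.bed")
    paths["dmrs_bed"] = _write_dmrs_bed(genome.annotations.dmrs, out / "dmrs.bed")
    paths["repeats_bed"] = _write_repeats_bed(genome.annotations.repeats, out / "repeats.bed")
    paths["truth"] = _write_truth_tsv(genome, out / "truth_genes.tsv")
    if config is not None:
        paths["truth_peaks"] = _write_truth_peaks(genome, config, out / "truth_peaks.bed")

    for track, recs in reads.items():
        path = out / _track_filename(track)
        _write_sam(genome, track, recs, path)
        paths[f"sam_{track}"] = path
    return paths


def _write_vcf(genome: DiploidGenome, path: Path) -> Path:
    order = {c: i for i, c in enumerate(genome.chrom_names)}
    snps = sorted(genome.snps, key=lambda s: (order[s.chrom], s.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=imprintscan-simulator\n")
        for c in genome.chrom_names:
            fh.write(f"##contig=<ID={c},length={genome.chrom_length(c)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##phasing=maternal_is_REF\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tF1\n")
        for s in snps:
            fh.write(f"{s.chrom}\t{s.pos + 1}\t.\t{s.maternal_base}\t{s.paternal_base}"
                     f"\t.\tPASS\t.\tGT\t0|1\n")
    return path


def _write_genes_bed(genes: Sequence[GeneModel], path: Path) -> Path:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")
    return path


def _write_cgis_bed(cgis: Sequence[CgiInterval], path: Path) -> Path:
    with open(path, "w") as fh:
        for c in cgis:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.name}\t0\t.\t{c.kind}"
                     f"\t{int(c.methylated)}\n")
    return path


def _write_dmrs_bed(dmrs: Sequence[DmrInterval], path: Path) -> Path:
    with open(path, "w") as fh:
        for d in dmrs:
            genes = ",".join(d.regulated_genes)
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.name}\t0\t.\t"
                     f"{d.methylated_parent}\t{genes}\n")
    return path


def _write_repeats_bed(repeats: Sequence[GenomeInterval], path: Path) -> Path:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t.\t{r.kind}\n")
    return path


def _write_truth_tsv(genome: DiploidGenome, path: Path) -> Path:
    from .synthetic_data import expected_allele_table, ko_fraction_table

    expected = expected_allele_table(genome)
    ko = ko_fraction_table(genome)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["name", "chrom", "start", "end", "strand", "expressed",
                    "maternal_fraction", "ko_maternal_fraction", "expected_allele"])
        for g in genome.annotations.genes:
            w.writerow([
                g.name, g.chrom, g.start, g.end, g.strand, int(g.expressed),
                repr(g.maternal_fraction),
                repr(ko[g.name]) if g.name in ko else "",
                expected.get(g.name, ""),
            ])
    return path


def _write_truth_peaks(genome: DiploidGenome, config: SimulationConfig, path: Path) -> Path:
    from .synthetic_data import mark_enriched_intervals

    with open(path, "w") as fh:
        for mark in config.marks:
            for iv, fold in mark_enriched_intervals(genome, mark, config):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t.\t"
                         f"{mark}\t{fold:.6g}\n")
    return path


def _write_sam(genome: DiploidGenome, track: str, reads: Sequence[ReadRecord],
               path: Path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": genome.chrom_length(c)} for c in genome.chrom_names],
        "CO": [f"track:{track}"],
    }
    tid = {c: i for i, c in enumerate(genome.chrom_names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"{track}_{i}"
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = tid[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = 60
            a.cigartuples = [(0, r.end - r.start)]
            hap = r.haplotype if r.haplotype is not None else 0
            a.query_sequence = genome.haplotype_seq(hap, r.chrom)[r.start:r.end]
            a.set_tag("XH", hap, "i")
            fh.write(a)


def read_fixtures(fixture_dir: str | Path) -> tuple[DiploidGenome, dict[str, list[ReadRecord]]]:
    """Load a fixture directory back into the in-memory object graph.

    SNP bases in reads are decoded from the SAM read sequences (the same
    path a real aligner-output consumer would take), not from truth tags.
    """
    d = Path(fixture_dir)
    maternal = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(d / "maternal.fa"), "fasta")}
    paternal = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(d / "paternal.fa"), "fasta")}
    chrom_names = list(maternal)

    snps: list[SnpRecord] = []
    with pysam.VariantFile(str(d / "snps.vcf")) as vf:
        for rec in vf:
            snps.append(SnpRecord(rec.chrom, rec.pos - 1, rec.ref, rec.alts[0]))

    genes: list[GeneModel] = []
    expected: dict[str, str] = {}
    ko: dict[str, float] = {}
    with open(d / "truth_genes.tsv") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            genes.append(GeneModel(
                row["chrom"], int(row["start"]), int(row["end"]), row["strand"],
                row["name"], bool(int(row["expressed"])), float(row["maternal_fraction"]),
            ))
            if row["expected_allele"]:
                expected[row["name"]] = row["expected_allele"]
            if row["ko_maternal_fraction"]:
                ko[row["name"]] = float(row["ko_maternal_fraction"])

    def bed_rows(name: str):
        with open(d / name) as fh:
            for line in fh:
                if line.strip():
                    yield line.rstrip("\n").split("\t")

    cgis = [CgiInterval(f[0], int(f[1]), int(f[2]), name=f[3], kind=f[6],
                        methylated=bool(int(f[7])))
            for f in bed_rows("cgis.bed")]
    dmrs = [DmrInterval(f[0], int(f[1]), int(f[2]), name=f[3], kind="dmr",
                        methylated_parent=f[6],
                        regulated_genes=tuple(f[7].split(",")) if f[7] else ())
            for f in bed_rows("dmrs.bed")]
    repeats = [GenomeInterval(f[0], int(f[1]), int(f[2]), name=f[3], kind=f[6])
               for f in bed_rows("repeats.bed")]

    ann = GenomeAnnotation(genes=genes, cgis=cgis, repeats=repeats, dmrs=dmrs)
    ann.expected_allele = expected  # type: ignore[attr-defined]
    ann.ko_maternal_fraction = ko  # type: ignore[attr-defined]
    genome = DiploidGenome(chrom_names, maternal, paternal, snps, ann)

    snp_index = SnpIndex(snps)
    reads: dict[str, list[ReadRecord]] = {}
    for path in sorted(d.glob("reads_*.sam")):
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            track = ""
            for co in fh.header.get("CO", []):
                if co.startswith("track:"):
                    track = co[len("track:"):]
            recs: list[ReadRecord] = []
            for a in fh:
                start, end = a.reference_start, a.reference_end
                seq = a.query_sequence
                pos, _, _ = snp_index.in_span(a.reference_name, start, end)
                bases = {int(p): seq[p - start] for p in pos} if len(pos) else None
                recs.append(ReadRecord(
                    a.reference_name, start, end, "-" if a.is_reverse else "+",
                    track=track, bases_at_snps=bases,
                    haplotype=a.get_tag("XH") if a.has_tag("XH") else None,
                ))
            reads[track or path.stem] = recs
    return genome, reads
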