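"""Synthetic diploid genome and read simulator.

Emulates the data structure of an F1 cross between two inbred strains
(maternal x paternal) profiled by ChIP-seq and strand-specific RNA-seq:

* two haplotype sequences differing only at phased SNPs;
* imprinted loci: a gene hosting an intragenic, methylated CGI/DMR, with
  heterochromatic marks (ATRX, H3.3, H3K9me3, H4K20me3) biased toward the
  methylated allele and H3K4me3 toward the other;
* parentally skewed expression of imprinted genes, balanced elsewhere;
* a KO condition in which a subset of DMR-regulated genes is de-repressed
  (expected-allele fraction shifted toward 0.5);
* uniform background reads everywhere else.

Reads are emitted pre-placed at their true coordinates; alignment, sequencing
error, PCR duplicates and mappability bias are out of scope.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .config import DUTP, SimulationConfig
from .model import (
    MATERNAL,
    PATERNAL,
    CgiInterval,
    DiploidGenome,
    DmrInterval,
    GeneModel,
    GenomeAnnotation,
    GenomeInterval,
    ReadRecord,
)
from .snps import SnpIndex

_BASES = np.array(list("ACGT"), dtype="<U1")

CONDITIONS = ("WT", "KO")
FRACTIONS = ("polyA+", "polyA-")


def _label_int(label: str) -> int:
    return zlib.crc32(label.encode())


def _track_rng(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, track label)."""
    return np.random.default_rng(np.random.SeedSequence([seed, _label_int(label)]))


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def build_genome(config: SimulationConfig) -> DiploidGenome:
    """Deterministically build a diploid genome from the layout config.

    Every imprinted gene hosts one intragenic DMR overlapping exactly one
    methylated CGI, with SNPs forced inside the DMR so allelic read
    assignment has something to work with.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = list(config.chrom_lengths)

    genes: list[GeneModel] = []
    cgis: list[CgiInterval] = []
    repeats: list[GenomeInterval] = []
    gene_slots: dict[str, list[tuple[int, int]]] = {}
    gaps: dict[str, list[tuple[int, int]]] = {}

    for chrom in chroms:
        length = config.chrom_lengths[chrom]
        peri = (0, config.pericentric_length)
        telo = (length - config.telomeric_length, length)
        repeats.append(GenomeInterval(chrom, *peri, name=f"{chrom}_peri", kind="pericentric"))
        repeats.append(GenomeInterval(chrom, *telo, name=f"{chrom}_telo", kind="telomeric"))

        region_start = peri[1] + 2_000
        region_end = telo[0] - 2_000
        slot = (region_end - region_start) / config.genes_per_chrom
        if slot < config.gene_length + 300:
            raise ValueError(
                f"{chrom}: {config.genes_per_chrom} genes of {config.gene_length} bp "
                "do not fit the configured chromosome length"
            )
        gene_slots[chrom] = []
        gaps[chrom] = []
        for i in range(config.genes_per_chrom):
            s0 = region_start + round(i * slot)
            gene_slots[chrom].append((s0, s0 + config.gene_length))
            gaps[chrom].append((s0 + config.gene_length, region_start + round((i + 1) * slot)))

    # genes (strand and expression flags drawn before imprinting overrides)
    flat_slots = [(chrom, s, e) for chrom in chroms for (s, e) in gene_slots[chrom]]
    n_genes = len(flat_slots)
    strands = rng.integers(0, 2, size=n_genes)
    expressed = rng.random(n_genes) < config.expressed_fraction

    imprinted_idx = sorted(
        {int(k * n_genes / config.n_imprinted) for k in range(config.n_imprinted)}
    ) if config.n_imprinted else []
    if len(imprinted_idx) != config.n_imprinted:
        raise ValueError("too few genes for the requested number of imprinted loci")

    dmrs: list[DmrInterval] = []
    expected_allele: dict[str, str] = {}
    ko_table: dict[str, float] = {}
    imprinted_set = set(imprinted_idx)
    ko_set = (
        {imprinted_idx[int(j * config.n_imprinted / config.n_ko_disrupted)]
         for j in range(config.n_ko_disrupted)}
        if config.n_ko_disrupted
        else set()
    )

    for gi, (chrom, gstart, gend) in enumerate(flat_slots):
        name = f"{chrom}_g{gi:04d}"
        if gi in imprinted_set:
            k = imprinted_idx.index(gi)
            exp_allele = MATERNAL if k % 2 == 0 else PATERNAL
            mf = config.imprinted_skew if exp_allele == MATERNAL else 1 - config.imprinted_skew
            gene = GeneModel(chrom, gstart, gend, "+-"[strands[gi]], name, True, mf)
            expected_allele[name] = exp_allele
            # the methylated (heterochromatic) allele is the silenced one
            meth_parent = PATERNAL if exp_allele == MATERNAL else MATERNAL
            dstart = gstart + (config.gene_length - config.dmr_length) // 2
            dmr = DmrInterval(
                chrom, dstart, dstart + config.dmr_length,
                name=f"DMR_{name}", kind="dmr",
                methylated_parent=meth_parent, regulated_genes=(name,),
            )
            dmrs.append(dmr)
            clen = min(config.cgi_length, config.dmr_length - 40)
            cstart = dstart + (config.dmr_length - clen) // 2
            cgis.append(CgiInterval(chrom, cstart, cstart + clen,
                                    name=f"CGI_{name}", kind="dmr_cgi", methylated=True))
            if gi in ko_set:
                shift = config.ko_shift if exp_allele == MATERNAL else -config.ko_shift
                ko_table[name] = float(np.clip(mf - shift, 0.0, 1.0))
        else:
            gene = GeneModel(chrom, gstart, gend, "+-"[strands[gi]], name,
                             bool(expressed[gi]), 0.5)
        genes.append(gene)

    # promoter CGIs at a fraction of non-imprinted genes
    promo_draw = rng.random(n_genes)
    half = config.cgi_length // 2
    for gi, gene in enumerate(genes):
        if gi in imprinted_set or promo_draw[gi] >= config.promoter_cgi_fraction:
            continue
        cstart = max(0, gene.tss - half)
        cgis.append(CgiInterval(gene.chrom, cstart, cstart + config.cgi_length,
                                name=f"CGI_p_{gene.name}", kind="promoter_cgi",
                                methylated=False))

    # interspersed repeats and intergenic CGIs parcelled into intergenic gaps
    for chrom in chroms:
        demands = (
            [("ervk", config.interspersed_repeat_length)] * config.ervk_per_chrom
            + [("line", config.interspersed_repeat_length)] * config.line_per_chrom
            + [("intergenic_cgi", config.cgi_length)] * config.intergenic_cgis_per_chrom
        )
        if not demands:
            continue
        chrom_gaps = gaps[chrom]
        if len(demands) > len(chrom_gaps):
            raise ValueError(f"{chrom}: not enough intergenic space for repeats/CGIs")
        step = len(chrom_gaps) / len(demands)
        meth_draw = rng.random(len(demands))
        for k, (kind, flen) in enumerate(demands):
            gs, ge = chrom_gaps[int((k + 0.5) * step)]
            # 400 bp margins keep gap features clear of promoter CGIs that
            # spill over gene boundaries
            if ge - gs < flen + 800:
                raise ValueError(f"{chrom}: intergenic gap too small for {kind}")
            fs = gs + 400
            if kind == "intergenic_cgi":
                cgis.append(CgiInterval(chrom, fs, fs + flen,
                                        name=f"{chrom}_icgi{k}", kind="intergenic_cgi",
                                        methylated=bool(meth_draw[k] < 0.3)))
            else:
                repeats.append(GenomeInterval(chrom, fs, fs + flen,
                                              name=f"{chrom}_{kind}{k}", kind=kind))

    # sequences and SNPs
    maternal: dict[str, str] = {}
    paternal: dict[str, str] = {}
    snp_records = []
    for chrom in chroms:
        length = config.chrom_lengths[chrom]
        mat = _random_sequence(rng, length)
        pat = mat.copy()
        positions: np.ndarray
        if config.snp_rate > 0:
            pos_set = set(np.flatnonzero(rng.random(length) < config.snp_rate).tolist())
            for dmr in dmrs:
                if dmr.chrom != chrom:
                    continue
                pos_set.update(
                    range(dmr.start + config.dmr_snp_spacing // 2, dmr.end,
                          config.dmr_snp_spacing)
                )
            positions = np.array(sorted(pos_set), dtype=np.int64)
        else:
            positions = np.array([], dtype=np.int64)
        if len(positions):
            # substitute a uniformly chosen different base on the paternal copy
            offsets = rng.integers(1, 4, size=len(positions))
            ref_idx = np.searchsorted(_BASES, mat[positions])
            pat[positions] = _BASES[(ref_idx + offsets) % 4]
            for p in range(len(positions)):
                snp_records.append(
                    _fast_snp(chrom, int(positions[p]), str(mat[positions[p]]),
                              str(pat[positions[p]]))
                )
        maternal[chrom] = "".join(mat.tolist())
        paternal[chrom] = "".join(pat.tolist())

    ann = GenomeAnnotation(genes=genes, cgis=cgis, repeats=repeats, dmrs=dmrs)
    ann.expected_allele = expected_allele  # type: ignore[attr-defined]
    ann.ko_maternal_fraction = ko_table  # type: ignore[attr-defined]
    return DiploidGenome(chroms, maternal, paternal, snp_records, ann)


def _fast_snp(chrom, pos, mb, pb):
    from .model import SnpRecord

    return SnpRecord(chrom, pos, mb, pb)


def ko_fraction_table(genome: DiploidGenome) -> dict[str, float]:
    return getattr(genome.annotations, "ko_maternal_fraction", {})


def expected_allele_table(genome: DiploidGenome) -> dict[str, str]:
    return getattr(genome.annotations, "expected_allele", {})


# ---------------------------------------------------------------------------
# ChIP-seq simulation
# ---------------------------------------------------------------------------

def mark_enriched_intervals(
    genome: DiploidGenome, mark: str, config: SimulationConfig
) -> list[tuple[GenomeInterval, float]]:
    """Ground-truth enriched intervals (fold > 1) for one chromatin mark."""
    if mark not in config.marks:
        raise ValueError(f"unknown mark {mark!r}")
    mc = config.marks[mark]
    out: list[tuple[GenomeInterval, float]] = []
    for dmr in genome.annotations.dmrs:
        if mc.fold_for("dmr") > 1:
            out.append((dmr, mc.fold_for("dmr")))
    for rep in genome.annotations.repeats:
        if mc.fold_for(rep.kind) > 1:
            out.append((rep, mc.fold_for(rep.kind)))
    for cgi in genome.annotations.cgis:
        if cgi.kind == "promoter_cgi" and mc.fold_for("promoter_cgi") > 1:
            out.append((cgi, mc.fold_for("promoter_cgi")))
    return out


def simulate_chip_track(
    genome: DiploidGenome,
    mark: str,
    config: SimulationConfig,
    depth: int | None = None,
    seed: int | None = None,
) -> list[ReadRecord]:
    """Draw exactly ``depth`` reads: uniform background, fold-x density inside
    the mark's enriched intervals, allele biased inside DMRs.

    A read overlapping a DMR is drawn from the DNA-methylated allele with
    probability ``dmr_bias``; elsewhere the allele is a fair coin. The read
    "sequence" is represented by the haplotype bases at every SNP the read
    covers, which is all the allelic assigner may see.
    """
    if mark not in config.marks:
        raise ValueError(f"unknown mark {mark!r}")
    mc = config.marks[mark]
    depth = config.chip_depth if depth is None else depth
    rng = _track_rng(config.seed if seed is None else seed, f"chip:{mark}")
    rl = config.read_length

    enriched = mark_enriched_intervals(genome, mark, config)
    by_chrom: dict[str, list[tuple[int, int, float]]] = {c: [] for c in genome.chrom_names}
    for iv, fold in enriched:
        by_chrom[iv.chrom].append((iv.start, iv.end, fold))

    segs: list[tuple[str, int, int]] = []
    weights: list[float] = []
    for chrom in genome.chrom_names:
        length = genome.chrom_length(chrom)
        cursor = 0
        for s, e, fold in sorted(by_chrom[chrom]):
            if s < cursor:
                raise ValueError("enriched intervals must be disjoint per mark")
            if s > cursor:
                segs.append((chrom, cursor, s))
                weights.append(s - cursor)
            segs.append((chrom, s, e))
            weights.append(fold * (e - s))
            cursor = e
        if cursor < length:
            segs.append((chrom, cursor, length))
            weights.append(length - cursor)

    w = np.asarray(weights, dtype=float)
    counts = rng.multinomial(depth, w / w.sum())

    # per-chromosome DMR lookup for allele bias
    dmr_lookup: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in genome.chrom_names:
        ds = sorted((d for d in genome.annotations.dmrs if d.chrom == chrom),
                    key=lambda d: d.start)
        dmr_lookup[chrom] = (
            np.array([d.start for d in ds], dtype=np.int64),
            np.array([d.end for d in ds], dtype=np.int64),
            np.array([d.methylated_parent == MATERNAL for d in ds], dtype=bool),
        )

    snp_index = SnpIndex(genome.snps)
    reads: list[ReadRecord] = []
    for (chrom, s, e), n in zip(segs, counts):
        if n == 0:
            continue
        length = genome.chrom_length(chrom)
        starts = s + (rng.random(n) * (e - s)).astype(np.int64)
        np.minimum(starts, length - rl, out=starts)
        ends = starts + rl

        dstart, dend, dmat = dmr_lookup[chrom]
        if len(dstart):
            idx = np.searchsorted(dend, starts, side="right")
            idx_c = np.minimum(idx, len(dstart) - 1)
            in_dmr = (idx < len(dstart)) & (dstart[idx_c] < ends)
            p_mat = np.where(
                in_dmr,
                np.where(dmat[idx_c], mc.dmr_bias, 1 - mc.dmr_bias),
                0.5,
            )
        else:
            p_mat = np.full(n, 0.5)
        hap = (rng.random(n) >= p_mat).astype(np.int8)  # 0 = maternal
        strand = rng.integers(0, 2, size=n)

        lo, hi = snp_index.range_indices(chrom, starts, ends)
        pos_arr = snp_index.pos.get(chrom)
        mb = snp_index.mbase.get(chrom)
        pb = snp_index.pbase.get(chrom)
        for i in range(n):
            bases = None
            if hi[i] > lo[i]:
                src = mb if hap[i] == 0 else pb
                bases = {int(pos_arr[j]): str(src[j]) for j in range(lo[i], hi[i])}
            reads.append(
                ReadRecord(chrom, int(starts[i]), int(ends[i]), "+-"[strand[i]],
                           track=mark, bases_at_snps=bases, haplotype=int(hap[i]))
            )
    return reads


# ---------------------------------------------------------------------------
# RNA-seq simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadBatch:
    """Columnar read set; iterates as :class:`ReadRecord` on demand.

    Large RNA-seq libraries stay as numpy arrays so allelic counting can run
    vectorized; ``to_records`` materializes plain records for code paths that
    want them.
    """

    chrom_names: list[str]
    chrom_id: np.ndarray
    start: np.ndarray
    end: np.ndarray
    strand_plus: np.ndarray
    hap: np.ndarray
    gene_idx: np.ndarray
    genes: list[GeneModel]
    track: str
    snp_index: SnpIndex

    def __len__(self) -> int:
        return len(self.start)

    def __iter__(self) -> Iterator[ReadRecord]:
        for i in range(len(self)):
            chrom = self.chrom_names[self.chrom_id[i]]
            pos, mb, pb = self.snp_index.in_span(chrom, int(self.start[i]), int(self.end[i]))
            bases = None
            if len(pos):
                src = mb if self.hap[i] == 0 else pb
                bases = {int(p): str(b) for p, b in zip(pos, src)}
            yield ReadRecord(
                chrom, int(self.start[i]), int(self.end[i]),
                "+" if self.strand_plus[i] else "-",
                track=self.track, bases_at_snps=bases, haplotype=int(self.hap[i]),
            )

    def to_records(self) -> list[ReadRecord]:
        return list(self)


def simulate_rnaseq(
    genome: DiploidGenome,
    condition: str = "WT",
    fraction: str = "polyA+",
    config: SimulationConfig | None = None,
    depth: int | None = None,
    seed: int | None = None,
) -> ReadBatch:
    """Strand-specific RNA-seq from expressed genes only.

    Per-read parental origin is Bernoulli(maternal_fraction) of the gene; in
    the KO condition DMR-regulated genes use the de-repressed fraction table.
    Read strand follows the configured library convention (dUTP: opposite to
    the transcript strand). Both PolyA fractions share the generative model;
    the label tags the track.
    """
    assert config is not None, "config is required"
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if fraction not in FRACTIONS:
        raise ValueError(f"unknown fraction {fraction!r}")
    depth = config.rna_depth if depth is None else depth
    rng = _track_rng(config.seed if seed is None else seed, f"rna:{condition}:{fraction}")
    rl = config.read_length

    genes = [g for g in genome.annotations.genes if g.expressed and len_span(g) > rl]
    track = f"RNA_{condition}_{fraction}"
    chrom_of = {c: i for i, c in enumerate(genome.chrom_names)}
    snp_index = SnpIndex(genome.snps)
    if not genes:
        empty = np.array([], dtype=np.int64)
        return ReadBatch(genome.chrom_names, empty.astype(np.int16), empty, empty,
                         empty.astype(bool), empty.astype(np.int8),
                         empty.astype(np.int32), genes, track, snp_index)

    ko = ko_fraction_table(genome) if condition == "KO" else {}
    spans = np.array([g.end - g.start - rl + 1 for g in genes], dtype=np.int64)
    weights = spans / spans.sum()
    counts = rng.multinomial(depth, weights)

    gene_idx = np.repeat(np.arange(len(genes), dtype=np.int32), counts)
    gstart = np.repeat(np.array([g.start for g in genes], dtype=np.int64), counts)
    gspan = np.repeat(spans, counts)
    mf = np.repeat(
        np.array([ko.get(g.name, g.maternal_fraction) for g in genes]), counts
    )
    tx_plus = np.repeat(np.array([g.strand == "+" for g in genes], dtype=bool), counts)
    chrom_id = np.repeat(
        np.array([chrom_of[g.chrom] for g in genes], dtype=np.int16), counts
    )

    start = gstart + (rng.random(len(gene_idx)) * gspan).astype(np.int64)
    hap = (rng.random(len(gene_idx)) >= mf).astype(np.int8)  # 0 = maternal
    strand_plus = ~tx_plus if config.strand_convention == DUTP else tx_plus

    return ReadBatch(genome.chrom_names, chrom_id, start, start + rl, strand_plus,
                     hap, gene_idx, genes, track, snp_index)


def len_span(g: GeneModel) -> int:
    return g.end - g.start
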