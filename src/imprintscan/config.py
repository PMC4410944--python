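"""Simulation and pipeline configuration.

The defaults here ARE the study conditions the test-suite and the analysis
scripts run under: an F1-style diploid genome (two inbred strains, dense
strain-distinguishing SNPs), imprinted DMRs carrying ATRX/H3.3/H3K9me3/
H4K20me3 on the methylated allele and H3K4me3 on the other, genes with
parentally skewed expression, and uniform background reads elsewhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

# annotation classes a chromatin mark can be enriched over
ENRICHMENT_CLASSES = (
    "dmr",
    "pericentric",
    "telomeric",
    "ervk",
    "line",
    "promoter_cgi",
)

DUTP = "dUTP"  # read strand opposite to transcript strand
SAME = "same"  # read strand equals transcript strand


@dataclass
class MarkConfig:
    """Enrichment folds per annotation class and allelic bias inside DMRs.

    ``dmr_bias`` is the probability that a read placed inside a DMR comes
    from the DNA-methylated allele: >0.5 for heterochromatic marks
    (ATRX/H3.3/H3K9me3/H4K20me3), <0.5 for the active-allele H3K4me3 mark,
    0.5 for input.
    """

    fold: dict[str, float] = field(default_factory=dict)
    dmr_bias: float = 0.5

    def validate(self, name: str) -> None:
        for cls, f in self.fold.items():
            if cls not in ENRICHMENT_CLASSES:
                raise ValueError(f"mark {name}: unknown enrichment class {cls!r}")
            if f < 1:
                raise ValueError(f"mark {name}: fold for {cls} must be >= 1")
        if not 0.0 <= self.dmr_bias <= 1.0:
            raise ValueError(f"mark {name}: dmr_bias must lie in [0,1]")

    def fold_for(self, cls: str) -> float:
        return self.fold.get(cls, 1.0)


def default_marks() -> dict[str, MarkConfig]:
    het = {"dmr": 8.0, "pericentric": 8.0, "telomeric": 6.0, "ervk": 6.0}
    return {
        "ATRX": MarkConfig(fold=dict(het), dmr_bias=0.9),
        "H3.3": MarkConfig(fold={**het, "promoter_cgi": 2.0}, dmr_bias=0.85),
        "H3K9me3": MarkConfig(fold=dict(het), dmr_bias=0.9),
        "H4K20me3": MarkConfig(fold={"dmr": 6.0, "pericentric": 6.0, "telomeric": 5.0, "ervk": 5.0}, dmr_bias=0.85),
        "H3K4me3": MarkConfig(fold={"promoter_cgi": 6.0, "dmr": 6.0}, dmr_bias=0.1),
        "input": MarkConfig(fold={}, dmr_bias=0.5),
    }


@dataclass
class SimulationConfig:
    """Layout and sampling parameters for the synthetic diploid genome."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 220_000, "chr2": 200_000}
    )
    read_length: int = 50
    snp_rate: float = 1 / 500  # genome-wide strain SNP density per bp

    # gene layout
    genes_per_chrom: int = 30
    gene_length: int = 3_000
    expressed_fraction: float = 0.9
    promoter_cgi_fraction: float = 0.5
    intergenic_cgis_per_chrom: int = 4
    cgi_length: int = 600

    # imprinting layout
    n_imprinted: int = 18
    imprinted_skew: float = 0.9  # expression fraction from the expected allele
    dmr_length: int = 800
    dmr_snp_spacing: int = 200  # SNPs forced inside every DMR at this spacing
    n_ko_disrupted: int = 5
    ko_shift: float = 0.3  # KO moves expected-allele fraction toward 0.5 by this

    # repeats layout
    pericentric_length: int = 10_000
    telomeric_length: int = 4_000
    ervk_per_chrom: int = 5
    line_per_chrom: int = 5
    interspersed_repeat_length: int = 1_500

    # sequencing
    marks: dict[str, MarkConfig] = field(default_factory=default_marks)
    chip_depth: int = 60_000  # reads per ChIP track
    rna_depth: int = 500_000  # reads per RNA-seq library
    strand_convention: str = DUTP

    def validate(self) -> None:
        if self.read_length <= 0 or self.snp_rate < 0:
            raise ValueError("read_length must be positive, snp_rate non-negative")
        if self.snp_rate > 0.25:
            raise ValueError("snp_rate too high to place isolated SNPs")
        if self.chip_depth <= 0 or self.rna_depth <= 0:
            raise ValueError("library depth must be positive")
        if not 0 <= self.imprinted_skew <= 1:
            raise ValueError("imprinted_skew must lie in [0,1]")
        if self.strand_convention not in (DUTP, SAME):
            raise ValueError(f"unknown strand convention {self.strand_convention!r}")
        if self.n_ko_disrupted > self.n_imprinted:
            raise ValueError("cannot disrupt more genes than are imprinted")
        for name, mc in self.marks.items():
            mc.validate(name)
        for chrom, length in self.chrom_lengths.items():
            if length < 2 * (self.pericentric_length + self.telomeric_length):
                raise ValueError(f"{chrom} too short for the configured layout")


def demo_config(seed: int = 0) -> SimulationConfig:
    """The default demo genome: 2 chromosomes, 18 imprinted loci."""
    return SimulationConfig(seed=seed)


def random_panel_config(
    seed: int = 0,
    n_genes: int = 1_500,
    n_imprinted: int = 0,
    gene_length: int = 500,
    reads_per_gene: int = 300,
) -> SimulationConfig:
    """A control panel of unskewed genes used for the parental-skew baseline.

    Genes are short, SNP-dense (1 SNP / 25 bp, so nearly every 50-bp read is
    informative and per-gene informative depth is even) and packed on one
    chromosome; no repeats or CGIs.
    """
    spacing = 340  # keeps gene slots comfortably larger than the gene bodies
    dmr_len = 240
    length = max(60_000, n_genes * (gene_length + spacing) + 20_000)
    cfg = SimulationConfig(
        seed=seed,
        chrom_lengths={"chr1": length},
        snp_rate=1 / 25,
        genes_per_chrom=n_genes,
        gene_length=gene_length,
        expressed_fraction=1.0,
        promoter_cgi_fraction=0.0,
        intergenic_cgis_per_chrom=0,
        n_imprinted=n_imprinted,
        dmr_length=dmr_len,
        dmr_snp_spacing=60,
        pericentric_length=2_000,
        telomeric_length=1_000,
        ervk_per_chrom=0,
        line_per_chrom=0,
        rna_depth=n_genes * reads_per_gene,
    )
    cfg.n_ko_disrupted = 5 if n_imprinted >= 5 else 0
    return cfg


@dataclass
class Thresholds:
    """Decision thresholds; defaults are the published cutoffs."""

    informative_floor: int = 50  # strict: > 50 informative SNP reads kept
    skew_strong: float = 0.66  # strict: > 66% skew toward expected allele
    skew_moderate: float = 0.60
    delta_disrupted: float = 0.10  # strict: WT/KO allelic shift > 10%
    repeat_fold: float = 2.0  # strict: ChIP/input fold > 2
    repeat_min_reads: int = 50  # strict: < 50 raw mapped reads excluded
    pct_low: float = 25.0
    pct_high: float = 75.0
    peak_window_bp: int = 1_000
    peak_fold: float = 2.0
    peak_merge_gap: int = 500
    peak_min_reads: int = 10
    promoter_window_bp: int = 1_000
    transcribed_min_rpkm: float = 1.0


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results/pipeline"
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulation: SimulationConfig = field(default_factory=demo_config)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        sim_raw = dict(raw.get("simulation", {}))
        marks_raw = sim_raw.pop("marks", None)
        sim = SimulationConfig(**sim_raw)
        if marks_raw is not None:
            sim.marks = {m: MarkConfig(**mc) for m, mc in marks_raw.items()}
        thr = Thresholds(**raw.get("thresholds", {}))
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "results/pipeline")),
            thresholds=thr,
            simulation=sim,
        )
        cfg.simulation.seed = cfg.simulation.seed or cfg.seed
        return cfg
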