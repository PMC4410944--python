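"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open throughout the package; 1-based
coordinates appear only at the VCF/SAM boundary in :mod:`imprintscan.io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

VALID_BASES = frozenset("ACGT")
MATERNAL = "maternal"
PATERNAL = "paternal"


@dataclass(frozen=True)
class GenomeInterval:
    """A genomic span. ``kind`` carries the annotation class (e.g. an
    enrichment class such as ``"dmr"`` or a repeat family such as ``"ERVK"``)."""

    chrom: str
    start: int
    end: int
    name: str = ""
    kind: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and start < self.end and end > self.start


@dataclass(frozen=True)
class CgiInterval(GenomeInterval):
    """A CpG island with its DNA-methylation status (an input annotation;
    methylation calling is upstream of this package)."""

    methylated: bool = False


@dataclass(frozen=True)
class DmrInterval(GenomeInterval):
    """An imprinted differentially methylated region.

    ``methylated_parent`` is the allele carrying DNA methylation (and, in the
    simulator, the heterochromatic marks). ``regulated_genes`` are the genes
    whose monoallelic expression this DMR governs.
    """

    methylated_parent: str = MATERNAL
    regulated_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.methylated_parent not in (MATERNAL, PATERNAL):
            raise ValueError(f"bad methylated_parent {self.methylated_parent!r}")


@dataclass(frozen=True)
class SnpRecord:
    """A phased strain-distinguishing SNP (F1 cross of two inbred strains)."""

    chrom: str
    pos: int
    maternal_base: str
    paternal_base: str

    def __post_init__(self) -> None:
        if self.maternal_base == self.paternal_base:
            raise ValueError(f"SNP at {self.chrom}:{self.pos} is not polymorphic")
        for b in (self.maternal_base, self.paternal_base):
            if b not in VALID_BASES:
                raise ValueError(f"bad base {b!r} at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class GeneModel:
    chrom: str
    start: int
    end: int
    strand: str
    name: str
    expressed: bool = True
    maternal_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid gene span {self.name}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.name}")
        if not 0.0 <= self.maternal_fraction <= 1.0:
            raise ValueError(f"maternal_fraction out of [0,1] for {self.name}")

    @property
    def tss(self) -> int:
        """Transcription start site (5' end in genome coordinates)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GenomeAnnotation:
    genes: list[GeneModel] = field(default_factory=list)
    cgis: list[CgiInterval] = field(default_factory=list)
    repeats: list[GenomeInterval] = field(default_factory=list)
    dmrs: list[DmrInterval] = field(default_factory=list)


@dataclass(slots=True)
class ReadRecord:
    """A placed sequencing read.

    ``bases_at_snps`` maps overlapped SNP positions to the base the read
    carries there — the only evidence the allelic assigner may use.
    ``haplotype`` (0 = maternal, 1 = paternal) is simulator ground truth,
    carried for parameter-recovery tests and never consulted by the analysis.
    """

    chrom: str
    start: int
    end: int
    strand: str
    track: str = ""
    bases_at_snps: dict[int, str] | None = None
    haplotype: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("read start must precede end")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class DiploidGenome:
    """Two haplotype sequences plus the phased SNP table and annotations.

    Invariant: the haplotypes have equal length per chromosome and differ
    exactly at the positions in ``snps``; ``validate()`` enforces this.
    """

    chrom_names: list[str]
    maternal_seq: dict[str, str]
    paternal_seq: dict[str, str]
    snps: list[SnpRecord]
    annotations: GenomeAnnotation

    def chrom_length(self, chrom: str) -> int:
        return len(self.maternal_seq[chrom])

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(self.maternal_seq[c]) for c in self.chrom_names}

    def validate(self) -> None:
        snp_positions: dict[str, set[int]] = {c: set() for c in self.chrom_names}
        for s in self.snps:
            if s.chrom not in self.maternal_seq:
                raise ValueError(f"SNP on unknown chromosome {s.chrom}")
            if not 0 <= s.pos < self.chrom_length(s.chrom):
                raise ValueError(f"SNP position {s.pos} out of bounds on {s.chrom}")
            if self.maternal_seq[s.chrom][s.pos] != s.maternal_base:
                raise ValueError(f"maternal base mismatch at {s.chrom}:{s.pos}")
            if self.paternal_seq[s.chrom][s.pos] != s.paternal_base:
                raise ValueError(f"paternal base mismatch at {s.chrom}:{s.pos}")
            snp_positions[s.chrom].add(s.pos)
        for c in self.chrom_names:
            m, p = self.maternal_seq[c], self.paternal_seq[c]
            if len(m) != len(p):
                raise ValueError(f"haplotype length mismatch on {c}")
            diffs = {i for i, (a, b) in enumerate(zip(m, p)) if a != b}
            if diffs != snp_positions[c]:
                raise ValueError(
                    f"haplotypes differ off the SNP table on {c}: "
                    f"{sorted(diffs ^ snp_positions[c])[:5]}..."
                )

    def haplotype_seq(self, hap: int, chrom: str) -> str:
        return self.maternal_seq[chrom] if hap == 0 else self.paternal_seq[chrom]


def swap_parents(snps: list[SnpRecord]) -> list[SnpRecord]:
    """Relabel maternal/paternal in a SNP table (symmetry checks)."""
    return [
        replace(s, maternal_base=s.paternal_base, paternal_base=s.maternal_base)
        for s in snps
    ]
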