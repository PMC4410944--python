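"""CGI positional classification and the sequential filter cascade.

CGIs are classified as promoter (overlapping a TSS window), intragenic
(within a gene body but clear of every TSS window) or intergenic. The
cascade applies feature filters in order — DNA methylation, heterochromatin
marks (H3K9me3 and H4K20me3), H3.3 enrichment, active transcription — and
records how the ATRX-bound and imprinted fractions evolve as the survivor
set shrinks toward ATRX-associated, imprinted CGIs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

from .model import CgiInterval, DmrInterval, GeneModel, GenomeInterval
from .quantify import IntervalProfile

PROMOTER, INTRAGENIC, INTERGENIC = "promoter", "intragenic", "intergenic"


def classify_cgi_position(
    cgi: GenomeInterval,
    genes: Sequence[GeneModel],
    promoter_window_bp: int = 1_000,
) -> str:
    """Promoter wins over intragenic when a CGI overlaps several genes."""
    in_body = False
    for g in genes:
        tss = g.tss
        if cgi.overlaps(g.chrom, max(0, tss - promoter_window_bp), tss + promoter_window_bp + 1):
            return PROMOTER
        if cgi.overlaps(g.chrom, g.start, g.end):
            in_body = True
    return INTRAGENIC if in_body else INTERGENIC


@dataclass
class CgiAnnotation:
    interval: CgiInterval
    position_class: str
    methylated: bool
    marks: IntervalProfile | None = None
    transcribed: bool = False
    atrx_bound: bool = False
    imprinted_dmr: DmrInterval | None = None

    def enriched(self, mark: str) -> bool:
        return bool(self.marks and self.marks.enriched.get(mark, False))


def annotate_cgis(
    cgis: Sequence[CgiInterval],
    genes: Sequence[GeneModel],
    atrx_peaks: Sequence[GenomeInterval],
    dmrs: Sequence[DmrInterval] = (),
    profiles: Sequence[IntervalProfile] = (),
    transcribed_genes: frozenset[str] | set[str] = frozenset(),
    promoter_window_bp: int = 1_000,
) -> list[CgiAnnotation]:
    """Bundle everything the cascade filters on.

    ``atrx_bound`` means >= 1 bp overlap with any ATRX peak; ``transcribed``
    means the CGI overlaps a gene in ``transcribed_genes`` (a set decided
    upstream from RNA-seq coverage).
    """
    profile_of = {p.interval: p for p in profiles}
    out = []
    for cgi in cgis:
        atrx = any(p.overlaps(cgi.chrom, cgi.start, cgi.end) for p in atrx_peaks)
        dmr = next((d for d in dmrs if d.overlaps(cgi.chrom, cgi.start, cgi.end)), None)
        txn = any(
            g.name in transcribed_genes and cgi.overlaps(g.chrom, g.start, g.end)
            for g in genes
        )
        out.append(CgiAnnotation(
            interval=cgi,
            position_class=classify_cgi_position(cgi, genes, promoter_window_bp),
            methylated=cgi.methylated,
            marks=profile_of.get(cgi),
            transcribed=txn,
            atrx_bound=atrx,
            imprinted_dmr=dmr,
        ))
    return out


@dataclass
class CascadeStage:
    name: str
    surviving: int
    fraction_atrx_bound: float | None
    fraction_imprinted: float | None


@dataclass
class FilterCascadeResult:
    stages: list[CascadeStage] = field(default_factory=list)
    survivors: list[list[CgiAnnotation]] = field(default_factory=list)


Predicate = Callable[[CgiAnnotation], bool]


def default_cascade() -> list[tuple[str, Predicate]]:
    return [
        ("methylated", lambda a: a.methylated),
        ("het_marks", lambda a: a.enriched("H3K9me3") and a.enriched("H4K20me3")),
        ("H3.3", lambda a: a.enriched("H3.3")),
        ("transcribed", lambda a: a.transcribed),
    ]


def _stage(name: str, annos: list[CgiAnnotation]) -> CascadeStage:
    n = len(annos)
    if n == 0:
        return CascadeStage(name, 0, None, None)
    atrx = sum(a.atrx_bound for a in annos)
    imp = sum(a.imprinted_dmr is not None for a in annos)
    return CascadeStage(name, n, atrx / n, imp / n)


def run_filter_cascade(
    cgis: Sequence[CgiAnnotation],
    order: Sequence[tuple[str, Predicate]] | None = None,
) -> FilterCascadeResult:
    """Apply filters sequentially; survivor sets are nested by construction."""
    order = default_cascade() if order is None else order
    result = FilterCascadeResult()
    current = list(cgis)
    result.stages.append(_stage("all", current))
    result.survivors.append(current)
    for name, pred in order:
        current = [a for a in current if pred(a)]
        result.stages.append(_stage(name, current))
        result.survivors.append(current)
    return result


def methylation_fraction(subset: Sequence[CgiAnnotation]) -> float | None:
    """Fraction of methylated CGIs; exact rational arithmetic, None if empty."""
    if not subset:
        return None
    frac = Fraction(sum(a.methylated for a in subset), len(subset))
    return float(frac)
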