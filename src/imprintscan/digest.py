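"""In-silico RFLP allelic discrimination.

A SNP that creates a restriction site on one parental allele but not the
other lets a PCR amplicon report allelic composition: digest, run a gel, and
compare the cut-fragment signal with the full-length band. This module
verifies a candidate SNP/enzyme pair is discriminating, predicts per-allele
fragment patterns, and converts band intensities into a cut-allele fraction
and an enrichment relative to input.

Band intensity defaults to the mass model (molar amount x fragment length),
matching intercalating-dye gel quantitation; a molar-proportional model is
available. Partial digestion is not modelled.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

from .model import DiploidGenome, MATERNAL, PATERNAL, SnpRecord

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

MASS, MOLAR = "mass", "molar"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _iupac_regex(site: str) -> re.Pattern:
    try:
        return re.compile("".join(f"[{IUPAC[b]}]" for b in site.upper()))
    except KeyError as exc:
        raise ValueError(f"bad IUPAC code in site {site!r}") from exc


def find_cut_sites(sequence: str, enzyme_site: str, cut_offset: int | None = None) -> list[int]:
    """0-based cut positions for every match on either strand.

    ``cut_offset`` is measured into the recognition sequence from its 5' end
    (blunt midpoint by default); reverse-orientation matches cut at the
    mirrored offset. Overlapping matches are found.
    """
    if not enzyme_site:
        raise ValueError("empty recognition site")
    k = len(enzyme_site)
    offset = k // 2 if cut_offset is None else cut_offset
    if not 0 <= offset <= k:
        raise ValueError("cut offset outside the recognition site")
    sequence = sequence.upper()
    fwd = _iupac_regex(enzyme_site)
    cuts = {m.start() + offset for m in _overlapping(fwd, sequence)}
    rc = reverse_complement(enzyme_site)
    if rc != enzyme_site.upper():
        rev = _iupac_regex(rc)
        cuts.update(m.start() + (k - offset) for m in _overlapping(rev, sequence))
    return sorted(c for c in cuts if 0 < c < len(sequence))


def _overlapping(pattern: re.Pattern, seq: str):
    pos = 0
    while True:
        m = pattern.search(seq, pos)
        if m is None:
            return
        yield m
        pos = m.start() + 1


def digest_lengths(sequence: str, enzyme_site: str, cut_offset: int | None = None) -> list[int]:
    """Fragment lengths after complete digestion; they sum to the input length."""
    cuts = find_cut_sites(sequence, enzyme_site, cut_offset)
    bounds = [0, *cuts, len(sequence)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


@dataclass
class DigestAssay:
    """A designed allelic-discrimination assay at one SNP."""

    snp: SnpRecord
    enzyme_site: str
    cut_offset: int | None
    amplicon_maternal: str
    amplicon_paternal: str
    cutting_allele: str  # maternal | paternal | both | neither
    fragments: dict[str, list[int]] = field(default_factory=dict)

    @property
    def usable(self) -> bool:
        return self.cutting_allele in (MATERNAL, PATERNAL)

    def amplicon(self, allele: str) -> str:
        return self.amplicon_maternal if allele == MATERNAL else self.amplicon_paternal


class AssayDesignError(ValueError):
    pass


def _locate_primer(seq: str, primer: str, what: str) -> int:
    hits = [m.start() for m in re.finditer(re.escape(primer), seq)]
    if len(hits) != 1:
        raise AssayDesignError(f"{what} primer matches {len(hits)} times, need exactly 1")
    return hits[0]


def design_assay(
    genome: DiploidGenome,
    snp: SnpRecord,
    primers: tuple[str, str],
    enzyme_site: str,
    cut_offset: int | None = None,
) -> DigestAssay:
    """Extract both allelic amplicons and derive which allele the enzyme cuts.

    The forward primer is given on the top strand, the reverse primer as its
    sequencing-order (bottom-strand) sequence; both must match exactly once
    on both haplotypes and bracket the SNP.
    """
    fwd, rev = primers
    rev_top = reverse_complement(rev)
    amplicons = {}
    for allele, seq in ((MATERNAL, genome.maternal_seq[snp.chrom]),
                        (PATERNAL, genome.paternal_seq[snp.chrom])):
        f = _locate_primer(seq, fwd, f"{allele} forward")
        r = _locate_primer(seq, rev_top, f"{allele} reverse")
        end = r + len(rev_top)
        if not f < r:
            raise AssayDesignError("primers are not in forward/reverse orientation")
        if not f <= snp.pos < end:
            raise AssayDesignError("amplicon does not span the SNP")
        amplicons[allele] = seq[f:end]

    frags = {a: digest_lengths(amplicons[a], enzyme_site, cut_offset) for a in amplicons}
    cut = {a: len(frags[a]) > 1 for a in amplicons}
    if cut[MATERNAL] and not cut[PATERNAL]:
        cutting = MATERNAL
    elif cut[PATERNAL] and not cut[MATERNAL]:
        cutting = PATERNAL
    elif cut[MATERNAL]:
        cutting = "both"
    else:
        cutting = "neither"
    return DigestAssay(snp, enzyme_site, cut_offset, amplicons[MATERNAL],
                       amplicons[PATERNAL], cutting, frags)


@dataclass
class BandQuantification:
    """Densitometry of one gel lane: fragment length -> summed intensity."""

    lane: str
    band_intensities: dict[int, float]

    def total(self) -> float:
        return sum(self.band_intensities.values())


def simulate_bands(
    assay: DigestAssay,
    cut_allele_fraction: float,
    lane: str = "sample",
    total_molar: float = 1.0,
    model: str = MASS,
) -> BandQuantification:
    """Ideal lane for a template pool with the given cut-allele molar fraction."""
    if not assay.usable:
        raise ValueError("assay does not discriminate alleles")
    if not 0.0 <= cut_allele_fraction <= 1.0:
        raise ValueError("cut_allele_fraction must lie in [0,1]")
    uncut = MATERNAL if assay.cutting_allele == PATERNAL else PATERNAL
    bands: dict[int, float] = {}
    for allele, molar in ((assay.cutting_allele, total_molar * cut_allele_fraction),
                          (uncut, total_molar * (1 - cut_allele_fraction))):
        for frag in assay.fragments[allele]:
            weight = molar * frag if model == MASS else molar
            bands[frag] = bands.get(frag, 0.0) + weight
    return BandQuantification(lane=lane, band_intensities=bands)


def allelic_fraction_from_bands(
    assay: DigestAssay, band: BandQuantification, model: str = MASS
) -> float:
    """Cut-allele molar fraction from band intensities.

    Totals are pooled over each allele's expected fragment set, so fragments
    of coinciding length within an allele are handled; the full-length
    (uncut) band never coincides with a cut fragment.
    """
    if model not in (MASS, MOLAR):
        raise ValueError(f"unknown intensity model {model!r}")
    uncut = MATERNAL if assay.cutting_allele == PATERNAL else PATERNAL
    cut_frags = assay.fragments[assay.cutting_allele]
    full_len = assay.fragments[uncut][0]
    cut_signal = sum(band.band_intensities.get(f, 0.0) for f in set(cut_frags))
    uncut_signal = band.band_intensities.get(full_len, 0.0)
    if model == MASS:
        cut_molar = cut_signal / sum(cut_frags)
        uncut_molar = uncut_signal / full_len
    else:
        cut_molar = cut_signal / len(cut_frags)
        uncut_molar = uncut_signal
    total = cut_molar + uncut_molar
    if total == 0:
        raise ValueError("empty lane")
    return cut_molar / total


def quantify_allelic(
    assay: DigestAssay,
    band: BandQuantification,
    input_band: BandQuantification,
    model: str = MASS,
) -> float:
    """Allelic enrichment of a ChIP lane relative to its input lane:
    ratio of cut-allele fractions."""
    sample_frac = allelic_fraction_from_bands(assay, band, model)
    input_frac = allelic_fraction_from_bands(assay, input_band, model)
    if input_frac == 0:
        raise ValueError("input lane shows no cut-allele signal")
    return sample_frac / input_frac
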