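"""Indexed access to the phased SNP table.

Backs both the read simulator (which writes haplotype bases into reads) and
the allelic counter (which reads them back out); lookups are binary searches
over per-chromosome sorted position arrays so they vectorize.
"""
from __future__ import annotations

import numpy as np

from .model import SnpRecord


class SnpIndex:
    def __init__(self, snps: list[SnpRecord]):
        by_chrom: dict[str, list[SnpRecord]] = {}
        for s in snps:
            by_chrom.setdefault(s.chrom, []).append(s)
        self.pos: dict[str, np.ndarray] = {}
        self.mbase: dict[str, np.ndarray] = {}
        self.pbase: dict[str, np.ndarray] = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda s: s.pos)
            self.pos[chrom] = np.array([s.pos for s in recs], dtype=np.int64)
            self.mbase[chrom] = np.array([s.maternal_base for s in recs], dtype="<U1")
            self.pbase[chrom] = np.array([s.paternal_base for s in recs], dtype="<U1")

    def __len__(self) -> int:
        return sum(len(p) for p in self.pos.values())

    def in_span(self, chrom: str, start: int, end: int):
        """(positions, maternal bases, paternal bases) of SNPs in [start, end)."""
        if chrom not in self.pos:
            empty = np.array([], dtype=np.int64)
            return empty, empty.astype("<U1"), empty.astype("<U1")
        p = self.pos[chrom]
        lo, hi = np.searchsorted(p, [start, end])
        return p[lo:hi], self.mbase[chrom][lo:hi], self.pbase[chrom][lo:hi]

    def range_indices(self, chrom: str, starts: np.ndarray, ends: np.ndarray):
        """Vectorized: index slices [lo, hi) of SNPs inside each span."""
        if chrom not in self.pos:
            z = np.zeros(len(starts), dtype=np.int64)
            return z, z.copy()
        p = self.pos[chrom]
        return np.searchsorted(p, starts), np.searchsorted(p, ends)
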