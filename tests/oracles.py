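"""Independent brute-force oracles the fast implementations are checked
against. Deliberately naive: O(n*m) scans, no indexing, no regex."""
from __future__ import annotations

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
         "N": "N"}


def naive_count(reads, intervals) -> dict:
    """O(n*m) overlap tally: >= 1 bp overlap on the same chromosome."""
    out = {iv: 0 for iv in intervals}
    for r in reads:
        for iv in intervals:
            if r.chrom == iv.chrom and r.start < iv.end and r.end > iv.start:
                out[iv] += 1
    return out


def naive_percentile_class(value: float, baseline) -> str:
    """Floor-type order-statistic percentiles with strict comparisons."""
    xs = sorted(baseline)
    n = len(xs)

    def pct(q: float) -> float:
        return xs[int(np.floor(q / 100 * (n - 1)))]

    if value < pct(25):
        return "low"
    if value > pct(75):
        return "high"
    return "mid"


def naive_revcomp(site: str) -> str:
    return "".join(_COMP[b] for b in reversed(site.upper()))


def _matches(window: str, site: str) -> bool:
    return len(window) == len(site) and all(
        w in IUPAC[s] for w, s in zip(window, site)
    )


def naive_cut_sites(seq: str, site: str, offset: int | None = None) -> list[int]:
    """Sliding-window scan of both strands; cut positions within (0, len)."""
    seq = seq.upper()
    site = site.upper()
    k = len(site)
    offset = k // 2 if offset is None else offset
    rc = naive_revcomp(site)
    cuts = set()
    for i in range(len(seq) - k + 1):
        window = seq[i: i + k]
        if _matches(window, site):
            cuts.add(i + offset)
        if rc != site and _matches(window, rc):
            cuts.add(i + (k - offset))
    return sorted(c for c in cuts if 0 < c < len(seq))


def naive_fragments(seq: str, site: str, offset: int | None = None) -> list[int]:
    cuts = naive_cut_sites(seq, site, offset)
    bounds = [0, *cuts, len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]
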