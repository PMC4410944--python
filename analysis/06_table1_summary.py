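#!/usr/bin/env python
"""Step 6 — the imprinted-DMR catalogue.

Parses the packaged 21-row DMR table (mm9 coordinates, parental methylation
origin, ATRX status, chromatin-mark levels) and tallies ATRX binding by DMR
class.
"""
import argparse
from pathlib import Path

from imprintscan.pipeline import _write_tsv
from imprintscan.table1 import read_table1, summarize_table1

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

records = read_table1()
s = summarize_table1(records)
args.out.mkdir(parents=True, exist_ok=True)
_write_tsv(args.out / "table1_summary.tsv",
           ["group", "count"],
           [["total", s.n_total],
            ["germline_total", s.germline_total],
            ["germline_atrx_yes", s.germline_yes],
            ["germline_atrx_mid", s.germline_mid],
            ["germline_atrx_no", s.germline_no],
            ["somatic_total", s.somatic_total],
            ["somatic_atrx_yes", s.somatic_yes],
            ["total_with_atrx_peak", s.total_with_peak]])
print(f"{s.total_with_peak} of {s.n_total} imprinted DMRs carry a called ATRX "
      f"peak ({s.total_with_peak / s.n_total:.0%})")
print(f"germline: {s.germline_yes} peak-called, {s.germline_mid} mid-level, "
      f"{s.germline_no} unbound; somatic: {s.somatic_yes} of {s.somatic_total}")
meth = sum(r.methylated for r in records)
print(f"{meth} of {s.n_total} DMRs are DNA-methylated in the catalogue")
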