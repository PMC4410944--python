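"""The packaged catalogue of mouse imprinted DMRs (mm9) with their ATRX
binding status and chromatin-mark levels, plus its reader and summary.

Mark levels are percentile classes relative to genomic CpG islands (low:
below the 25th percentile; high: above the 75th; mid between). ATRX status
"mid" means visible enrichment that did not reach a peak call.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

MARK_COLUMNS = {
    "H3.3": "h3_3",
    "Daxx": "daxx",
    "H3K9me3": "h3k9me3",
    "H4K20me3": "h4k20me3",
    "H3K4me3": "h3k4me3",
    "H3K27me3": "h3k27me3",
}
_LEVELS = {"low", "mid", "high"}
_ATRX = {"yes", "mid", "no"}
_KINDS = {"germline", "somatic"}
_PARENTS = {"maternal", "paternal"}


@dataclass
class DmrRecord:
    name: str
    chrom: str
    start: int
    end: int
    kind: str  # germline | somatic
    methylated_parent: str
    has_cgi: bool
    methylated: bool
    atrx_status: str  # yes | mid | no
    mark_levels: dict[str, str]


def _bool(field: str, value: str, row: str) -> bool:
    if value not in ("yes", "no"):
        raise ValueError(f"row {row!r}: bad {field} value {value!r}")
    return value == "yes"


def default_table1_path() -> Path:
    return Path(resources.files("imprintscan").joinpath("data/table1_dmrs.tsv"))  # type: ignore[arg-type]


def read_table1(path: str | Path | None = None) -> list[DmrRecord]:
    """Parse the packaged DMR table; rejects unknown enumerations, naming
    the offending row."""
    path = default_table1_path() if path is None else Path(path)
    records: list[DmrRecord] = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            name = row.get("name", "<unnamed>")
            try:
                start, end = int(row["start"]), int(row["end"])
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"row {name!r}: bad coordinates") from exc
            if not 0 < start < end:
                raise ValueError(f"row {name!r}: coordinates out of order")
            if row["kind"] not in _KINDS:
                raise ValueError(f"row {name!r}: bad kind {row['kind']!r}")
            if row["methylated_parent"] not in _PARENTS:
                raise ValueError(f"row {name!r}: bad parent {row['methylated_parent']!r}")
            if row["atrx"] not in _ATRX:
                raise ValueError(f"row {name!r}: bad ATRX status {row['atrx']!r}")
            levels = {}
            for mark, col in MARK_COLUMNS.items():
                level = row.get(col, "")
                if level not in _LEVELS:
                    raise ValueError(f"row {name!r}: bad {mark} level {level!r}")
                levels[mark] = level
            records.append(DmrRecord(
                name=name, chrom=row["chrom"], start=start, end=end,
                kind=row["kind"], methylated_parent=row["methylated_parent"],
                has_cgi=_bool("cpgi", row["cpgi"], name),
                methylated=_bool("methylated", row["methylated"], name),
                atrx_status=row["atrx"], mark_levels=levels,
            ))
    return records


@dataclass
class Table1Summary:
    n_total: int
    germline_total: int
    germline_yes: int
    germline_mid: int
    germline_no: int
    somatic_total: int
    somatic_yes: int

    @property
    def total_with_peak(self) -> int:
        """DMRs with a called ATRX peak (status "yes")."""
        return self.germline_yes + self.somatic_yes


def summarize_table1(records: list[DmrRecord]) -> Table1Summary:
    def tally(kind: str, status: str) -> int:
        return sum(r.kind == kind and r.atrx_status == status for r in records)

    return Table1Summary(
        n_total=len(records),
        germline_total=sum(r.kind == "germline" for r in records),
        germline_yes=tally("germline", "yes"),
        germline_mid=tally("germline", "mid"),
        germline_no=tally("germline", "no"),
        somatic_total=sum(r.kind == "somatic" for r in records),
        somatic_yes=tally("somatic", "yes"),
    )
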