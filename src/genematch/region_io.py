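"""Read region BED files and write the tabular association report.

BED coordinates are taken verbatim and treated as a 1-based inclusive
interval (region length = end - start + 1): the reported overlap
percentages are defined on that arithmetic. Columns beyond the third are
carried through untouched and re-emitted after the PercArea column.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import IO, Iterable

__all__ = [
    "BedParseError",
    "GenomicRegion",
    "Association",
    "REPORT_COLUMNS",
    "parse_bed",
    "write_report",
    "read_report",
    "format_percentage",
]

REPORT_COLUMNS = (
    "Region",
    "Midpoint",
    "Gene",
    "Transcript",
    "Exon",
    "Area",
    "Distance",
    "PercRegion",
    "PercArea",
)

_SKIP_PREFIXES = ("#", "track", "browser")


class BedParseError(ValueError):
    """Raised for malformed BED input; the message names the offending line."""


@dataclass(frozen=True)
class GenomicRegion:
    """One BED record. ``extra_columns`` are opaque pass-through strings."""

    chrom: str
    start: int
    end: int
    extra_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"region end {self.end} < start {self.start}")

    @property
    def region_id(self) -> str:
        return f"{self.chrom}_{self.start}_{self.end}"

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Association:
    """One output row: a region x gene x transcript x area association.

    ``perc_region`` / ``perc_area`` hold unrounded percentages (the
    aggregation-rule thresholds compare unrounded values); rounding to two
    decimals happens only when the report is written. ``perc_area`` is -1
    for areas without a fixed length (INTRON, UPSTREAM, DOWNSTREAM).
    ``exon_index`` is -1 for gene-level rows that tie several transcripts,
    in which case ``transcript_field`` comma-joins their identifiers.
    """

    region_id: str
    midpoint: int
    gene_id: str
    transcript_field: str
    exon_index: int
    area: str
    distance: int
    perc_region: float
    perc_area: float
    extras: tuple[str, ...] = ()


def parse_bed(lines: Iterable[str]) -> list[GenomicRegion]:
    """Parse BED lines into regions, preserving input order.

    Track/browser/comment lines are skipped. Lines are split on tabs; lines
    without tabs fall back to whitespace splitting.
    """
    regions: list[GenomicRegion] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(_SKIP_PREFIXES):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise BedParseError(
                f"line {lineno}: expected >= 3 columns, got {len(fields)}"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise BedParseError(
                f"line {lineno}: non-integer start/end "
                f"({fields[1]!r}, {fields[2]!r})"
            ) from None
        if end < start:
            raise BedParseError(f"line {lineno}: end {end} < start {start}")
        regions.append(
            GenomicRegion(
                chrom=fields[0],
                start=start,
                end=end,
                extra_columns=tuple(fields[3:]),
            )
        )
    return regions


def format_percentage(value: float) -> str:
    """Format a percentage with exactly two decimals, half away from zero.

    The sentinel -1 (undefined PercArea) is printed literally.
    """
    if value == -1:
        return "-1"
    return str(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def write_report(associations: Iterable[Association], sink: IO[str]) -> int:
    """Write the tab-separated report; returns the number of data rows."""
    sink.write("\t".join(REPORT_COLUMNS) + "\n")
    n = 0
    for a in associations:
        row = [
            a.region_id,
            str(a.midpoint),
            a.gene_id,
            a.transcript_field,
            str(a.exon_index),
            a.area,
            str(a.distance),
            format_percentage(a.perc_region),
            format_percentage(a.perc_area),
            *a.extras,
        ]
        sink.write("\t".join(row) + "\n")
        n += 1
    return n


def read_report(lines: Iterable[str]) -> list[Association]:
    """Parse a report written by :func:`write_report` back into rows.

    Percentages come back rounded as printed; intended for round-trip
    checks and downstream consumption, not to feed the aggregation rules.
    """
    rows: list[Association] = []
    it = iter(lines)
    header = next(it, None)
    if header is None:
        return rows
    for raw in it:
        line = raw.rstrip("\n")
        if not line:
            continue
        f = line.split("\t")
        rows.append(
            Association(
                region_id=f[0],
                midpoint=int(f[1]),
                gene_id=f[2],
                transcript_field=f[3],
                exon_index=int(f[4]),
                area=f[5],
                distance=int(f[6]),
                perc_region=float(f[7]),
                perc_area=float(f[8]),
                extras=tuple(f[9:]),
            )
        )
    return rows
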