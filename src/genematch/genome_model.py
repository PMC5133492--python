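"""Strand-aware gene / transcript / exon models parsed from GTF annotation.

Only ``exon`` feature lines are consumed: the downstream area decomposition
needs nothing but the exon structure of each transcript, plus the strand.
Coordinates are kept 1-based inclusive exactly as GTF states them.

Exons are numbered in transcript (5'->3') order: on the plus strand exon 1
is the leftmost exon, on the minus strand it is the rightmost one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator

__all__ = [
    "GtfParseError",
    "ExonInterval",
    "TranscriptModel",
    "GeneModel",
    "parse_gtf",
    "transcript_points",
    "to_gtf_lines",
]

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')
_STRANDS = frozenset("+-")


class GtfParseError(ValueError):
    """Raised for malformed GTF input; the message names the offending line."""


@dataclass(frozen=True, order=True)
class ExonInterval:
    """One exon: ``index`` is its 1-based position in transcript 5'->3' order."""

    index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")
        if self.index < 1:
            raise ValueError(f"exon index must be >= 1, got {self.index}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered tuple of disjoint exons on one strand.

    ``exons`` is in transcript (5'->3') order; ``tss_point`` / ``tts_point``
    are the 5'-most and 3'-most transcribed bases.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[ExonInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")

    @property
    def tss_point(self) -> int:
        """Genomic coordinate of the 5'-most transcribed base."""
        if self.strand == "+":
            return min(e.start for e in self.exons)
        return max(e.end for e in self.exons)

    @property
    def tts_point(self) -> int:
        """Genomic coordinate of the 3'-most transcribed base."""
        if self.strand == "+":
            return max(e.end for e in self.exons)
        return min(e.start for e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return (min(e.start for e in self.exons), max(e.end for e in self.exons))


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic interval covered by any exon of any transcript."""
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )


def transcript_points(transcript: TranscriptModel) -> tuple[int, int]:
    """Return ``(tss_point, tts_point)`` of a transcript."""
    return transcript.tss_point, transcript.tts_point


def parse_gtf(
    lines: Iterable[str],
    gene_tag: str = "gene_id",
    transcript_tag: str = "transcript_id",
) -> list[GeneModel]:
    """Parse GTF exon lines into :class:`GeneModel` objects.

    Parameters
    ----------
    lines
        Iterable of text lines (a file handle works). Comment lines (``#``)
        and non-``exon`` feature lines are skipped.
    gene_tag, transcript_tag
        Attribute keys whose values identify the gene and transcript of each
        exon line (Ensembl default: ``gene_id`` / ``transcript_id``).

    Returns
    -------
    list of GeneModel, sorted by (chrom, span start, gene id); transcripts
    within each gene sorted by transcript id. The result is therefore
    independent of the input line order.
    """
    # (gene, transcript) -> accumulated exon spec
    acc: dict[tuple[str, str], dict] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise GtfParseError(
                f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        if fields[2] != "exon":
            continue
        chrom = fields[0]
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError:
            raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
        strand = fields[6]
        if strand not in _STRANDS:
            raise GtfParseError(f"line {lineno}: unknown strand symbol {strand!r}")
        attrs = dict(_ATTR_RE.findall(fields[8]))
        for tag in (gene_tag, transcript_tag):
            if tag not in attrs:
                raise GtfParseError(
                    f"line {lineno}: exon line missing attribute tag {tag!r}"
                )
        key = (attrs[gene_tag], attrs[transcript_tag])
        rec = acc.setdefault(key, {"chrom": chrom, "strand": strand, "exons": []})
        if rec["chrom"] != chrom:
            raise GtfParseError(
                f"line {lineno}: transcript {key[1]!r} spans chromosomes "
                f"{rec['chrom']!r} and {chrom!r}"
            )
        if rec["strand"] != strand:
            raise GtfParseError(
                f"line {lineno}: transcript {key[1]!r} has inconsistent strand"
            )
        rec["exons"].append((start, end))

    by_gene: dict[str, list[TranscriptModel]] = {}
    for (gene_id, transcript_id), rec in acc.items():
        exons_lr = sorted(rec["exons"])  # left-to-right genomic order
        for (s1, e1), (s2, _e2) in zip(exons_lr, exons_lr[1:]):
            if s2 <= e1:
                raise GtfParseError(
                    f"transcript {transcript_id!r}: overlapping exons "
                    f"[{s1},{e1}] and [{s2},{_e2}]"
                )
        ordered = exons_lr if rec["strand"] == "+" else exons_lr[::-1]
        exons = tuple(
            ExonInterval(index=i, start=s, end=e)
            for i, (s, e) in enumerate(ordered, start=1)
        )
        by_gene.setdefault(gene_id, []).append(
            TranscriptModel(
                transcript_id=transcript_id,
                gene_id=gene_id,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=exons,
            )
        )

    genes = []
    for gene_id, transcripts in by_gene.items():
        chroms = {t.chrom for t in transcripts}
        strands = {t.strand for t in transcripts}
        if len(chroms) > 1:
            raise GtfParseError(
                f"gene {gene_id!r}: transcripts on multiple chromosomes {sorted(chroms)}"
            )
        if len(strands) > 1:
            raise GtfParseError(f"gene {gene_id!r}: transcripts on both strands")
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=transcripts[0].chrom,
                strand=transcripts[0].strand,
                transcripts=tuple(sorted(transcripts, key=lambda t: t.transcript_id)),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.span, g.gene_id))
    return genes


def to_gtf_lines(genes: Iterable[GeneModel], source: str = "genematch") -> Iterator[str]:
    """Serialize gene models back to GTF exon lines (round-trip safe)."""
    for gene in genes:
        for tr in gene.transcripts:
            for exon in tr.exons:
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tr.transcript_id}";'
                yield (
                    f"{gene.chrom}\t{source}\texon\t{exon.start}\t{exon.end}"
                    f"\t.\t{gene.strand}\t.\t{attrs}"
                )
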