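"""Decompose a transcript's neighborhood into eight disjoint labeled areas.

The transcript span is tiled exactly by 1st_EXON, GENE_BODY (every later
exon) and INTRON (every gap between consecutive exons). Upstream of the
transcription start site (TSS point) lie, in order of increasing distance,
the TSS area (width ``t``), the PROMOTER (width ``p``) and UPSTREAM (out to
the maximum association distance ``q``); downstream of the transcription
termination site lie the TTS area (width ``s``, zero and hence absent by
default) and DOWNSTREAM (out to ``q``). On the minus strand the layout is
the mirror image. Zero-width areas are omitted, and the five intergenic
areas are clipped against the transcript's own gene span, so that e.g. a
short isoform of a long gene contributes no DOWNSTREAM area inside the gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .genome_model import TranscriptModel

__all__ = [
    "TSS",
    "PROMOTER",
    "UPSTREAM",
    "FIRST_EXON",
    "INTRON",
    "GENE_BODY",
    "TTS",
    "DOWNSTREAM",
    "AREA_LABELS",
    "DEFAULT_PRIORITIES",
    "MatchConfig",
    "AreaInterval",
    "compute_areas",
]

TSS = "TSS"
PROMOTER = "PROMOTER"
UPSTREAM = "UPSTREAM"
FIRST_EXON = "1st_EXON"
INTRON = "INTRON"
GENE_BODY = "GENE_BODY"
TTS = "TTS"
DOWNSTREAM = "DOWNSTREAM"

AREA_LABELS = (TSS, PROMOTER, UPSTREAM, FIRST_EXON, INTRON, GENE_BODY, TTS, DOWNSTREAM)

#: Default tie-break ranking, most important first.
DEFAULT_PRIORITIES = (TSS, FIRST_EXON, PROMOTER, TTS, INTRON, GENE_BODY, UPSTREAM, DOWNSTREAM)

REPORT_LEVELS = ("exon", "transcript", "gene")


@dataclass(frozen=True)
class MatchConfig:
    """All tunable parameters of the matching algorithm.

    Attributes
    ----------
    t : int
        TSS area width in bp (default 200).
    p : int
        Promoter width in bp (default 1300).
    s : int
        TTS area width in bp (default 0, i.e. no TTS area).
    q : int
        Maximum region-gene association distance in bp (default 10000).
    w : float
        PercRegion threshold in percent for the aggregation rules (default 50).
    v : float
        PercArea threshold in percent for the aggregation rules (default 90).
    priorities : tuple of str
        Permutation of the eight area labels used to break ties.
    report_level : str
        One of ``exon`` (all overlapped areas), ``transcript`` (one area per
        region x transcript) or ``gene`` (one area per region x gene).
    gene_tag, transcript_tag : str
        GTF attribute keys naming the reported gene / transcript identifiers.
    """

    t: int = 200
    p: int = 1300
    s: int = 0
    q: int = 10_000
    w: float = 50.0
    v: float = 90.0
    priorities: tuple[str, ...] = DEFAULT_PRIORITIES
    report_level: str = "exon"
    gene_tag: str = "gene_id"
    transcript_tag: str = "transcript_id"

    def __post_init__(self) -> None:
        if min(self.t, self.p, self.s) < 0:
            raise ValueError("area widths t, p, s must be >= 0")
        if self.q <= self.t + self.p or self.q <= self.s:
            raise ValueError("max distance q must exceed t + p and s")
        if not (0 <= self.w <= 100 and 0 <= self.v <= 100):
            raise ValueError("thresholds w and v must lie in [0, 100]")
        if sorted(self.priorities) != sorted(AREA_LABELS):
            raise ValueError(
                "priorities must be a permutation of the eight area labels"
            )
        if self.report_level not in REPORT_LEVELS:
            raise ValueError(f"report_level must be one of {REPORT_LEVELS}")

    def priority_rank(self, area: str) -> int:
        return self.priorities.index(area)


@dataclass(frozen=True)
class AreaInterval:
    """One labeled gene area with its genomic extent.

    ``denom_length`` is the full area length used as the PercArea
    denominator; it is ``None`` for INTRON, UPSTREAM and DOWNSTREAM, whose
    extent is not a fixed property of the gene (PercArea is reported as -1
    for these).
    """

    label: str
    start: int
    end: int
    exon_index: int
    denom_length: Optional[int] = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _outside_gene_span(
    lo: int, hi: int, gene_span: tuple[int, int]
) -> Optional[tuple[int, int]]:
    """Intersect [lo, hi] with the complement of the gene span.

    Flank areas extend away from a point inside the gene span, so at most
    one side of the complement can be hit.
    """
    gs, ge = gene_span
    left = (lo, min(hi, gs - 1))
    right = (max(lo, ge + 1), hi)
    if left[0] <= left[1]:
        return left
    if right[0] <= right[1]:
        return right
    return None


def compute_areas(
    transcript: TranscriptModel,
    gene_span: tuple[int, int],
    config: MatchConfig,
) -> list[AreaInterval]:
    """Compute the disjoint area decomposition of one transcript.

    Exonic and intronic areas exactly tile the transcript span; the five
    intergenic flank areas are clipped to coordinate >= 1 and to the
    complement of ``gene_span`` (the transcript's own gene only — other
    genes never mask areas). Zero-width or fully clipped areas are omitted.

    Exon-index conventions for the output: TSS/PROMOTER/UPSTREAM carry
    index 1, TTS/DOWNSTREAM the last exon's index, GENE_BODY the overlapped
    exon's index, INTRON the index of the exon that follows the intron in
    transcript order.
    """
    areas: list[AreaInterval] = []
    exons = transcript.exons
    for exon in exons:
        label = FIRST_EXON if exon.index == 1 else GENE_BODY
        areas.append(
            AreaInterval(label, exon.start, exon.end, exon.index, exon.length)
        )
    for up, down in zip(exons, exons[1:]):  # consecutive in transcript order
        if transcript.strand == "+":
            lo, hi = up.end + 1, down.start - 1
        else:
            lo, hi = down.end + 1, up.start - 1
        if lo <= hi:
            areas.append(AreaInterval(INTRON, lo, hi, down.index, None))

    tss, tts = transcript.tss_point, transcript.tts_point
    t, p, s, q = config.t, config.p, config.s, config.q
    last_index = exons[-1].index
    if transcript.strand == "+":
        flanks = [
            (TSS, tss - t, tss - 1, 1, t),
            (PROMOTER, tss - t - p, tss - t - 1, 1, p),
            (UPSTREAM, tss - q, tss - t - p - 1, 1, None),
            (TTS, tts + 1, tts + s, last_index, s),
            (DOWNSTREAM, tts + s + 1, tts + q, last_index, None),
        ]
    else:
        flanks = [
            (TSS, tss + 1, tss + t, 1, t),
            (PROMOTER, tss + t + 1, tss + t + p, 1, p),
            (UPSTREAM, tss + t + p + 1, tss + q, 1, None),
            (TTS, tts - s, tts - 1, last_index, s),
            (DOWNSTREAM, tts - q, tts - s - 1, last_index, None),
        ]
    for label, lo, hi, exon_index, denom in flanks:
        lo = max(lo, 1)
        if lo > hi:
            continue
        clipped = _outside_gene_span(lo, hi, gene_span)
        if clipped is None:
            continue
        areas.append(AreaInterval(label, clipped[0], clipped[1], exon_index, denom))
    return areas
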