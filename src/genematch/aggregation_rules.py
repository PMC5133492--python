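"""Collapse exon-level associations to one area per transcript or gene.

The selection rules, applied per region x transcript:

1. If any area covers at least ``w`` percent of the region (PercRegion >= w,
   on unrounded values), the annotation is the such area with the highest
   PercRegion, ties broken by the priority ranking.
2. Otherwise, among areas the region covers at least ``v`` percent of
   (PercArea >= v; the -1 sentinel never qualifies), pick the highest
   PercRegion, ties by priorities.
3. Otherwise (no area meets either threshold) fall back to the highest
   PercRegion over all areas, ties by priorities.

At gene level the per-transcript winners of one gene compete by priority
rank; when several transcripts tie on the winning area, a single row is
emitted whose Transcript field comma-joins their identifiers and whose
Exon field is -1.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

from .area_annotation import MatchConfig
from .region_io import Association

__all__ = ["select_area", "aggregate_transcript_level", "aggregate_gene_level"]


def select_area(rows: Sequence[Association], config: MatchConfig) -> Association:
    """Pick the single annotation for one region x transcript.

    ``rows`` must be the non-empty exon-level rows of one region-transcript
    pair; the winning row is returned unchanged.
    """
    if not rows:
        raise ValueError("select_area requires at least one association row")
    pool = [r for r in rows if r.perc_region >= config.w]
    if not pool:
        pool = [r for r in rows if r.perc_area != -1 and r.perc_area >= config.v]
    if not pool:
        pool = list(rows)
    best = max(r.perc_region for r in pool)
    tied = [r for r in pool if r.perc_region == best]
    return min(tied, key=lambda r: config.priority_rank(r.area))


def _grouped(
    rows: Sequence[Association], key
) -> list[list[Association]]:
    """Group rows by key, preserving first-appearance order."""
    groups: dict = {}
    for row in rows:
        groups.setdefault(key(row), []).append(row)
    return list(groups.values())


def aggregate_transcript_level(
    exon_rows: Sequence[Association], config: MatchConfig
) -> list[Association]:
    """One row per (region, transcript), chosen by :func:`select_area`."""
    return [
        select_area(group, config)
        for group in _grouped(
            exon_rows, lambda r: (r.region_id, r.gene_id, r.transcript_field)
        )
    ]


def aggregate_gene_level(
    transcript_rows: Sequence[Association], config: MatchConfig
) -> list[Association]:
    """One row per (region, gene), resolving transcripts by area priority.

    Transcript rows must come from :func:`aggregate_transcript_level`.
    When several transcripts of a gene tie on the best-priority area, the
    emitted row joins their IDs with a comma (input order), sets the exon
    index to -1, and takes its percentages from the tied row with maximal
    PercRegion.
    """
    out: list[Association] = []
    for group in _grouped(transcript_rows, lambda r: (r.region_id, r.gene_id)):
        best_rank = min(config.priority_rank(r.area) for r in group)
        tied = [r for r in group if config.priority_rank(r.area) == best_rank]
        if len(tied) == 1:
            out.append(tied[0])
        else:
            source = max(tied, key=lambda r: r.perc_region)
            out.append(
                replace(
                    source,
                    transcript_field=",".join(r.transcript_field for r in tied),
                    exon_index=-1,
                )
            )
    return out
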