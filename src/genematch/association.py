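"""Exon-level association of regions with their closest gene(s).

A region is a candidate for a gene when the gene lies within the maximum
association distance ``q`` and at least one of its transcript areas
overlaps the region. Among candidates only the gene(s) at minimum distance
are kept — all of them in case of ties, which is how overlapping and
quasi-overlapping genes both end up reported. Distance is 0 whenever the
region intersects the gene span; otherwise it is the smallest number of
bases from the region midpoint to any transcript's TSS or TTS point.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .area_annotation import AreaInterval, MatchConfig, compute_areas
from .genome_model import GeneModel
from .region_io import Association, GenomicRegion

__all__ = [
    "overlap_length",
    "perc_region",
    "perc_area",
    "region_gene_distance",
    "GeneIndex",
    "match_region",
    "annotate_regions",
]


def overlap_length(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Shared bases of two 1-based inclusive intervals (0 when disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def perc_region(overlap: int, region_length: int) -> float:
    """Percentage of the region covered by an area (unrounded)."""
    return 100.0 * overlap / region_length


def perc_area(overlap: int, area: AreaInterval) -> float:
    """Percentage of the area covered by the region; -1 when undefined.

    Areas without a fixed length (INTRON, UPSTREAM, DOWNSTREAM) have no
    denominator and report the sentinel -1.
    """
    if area.denom_length is None:
        return -1.0
    return 100.0 * overlap / area.denom_length


def region_gene_distance(region: GenomicRegion, gene: GeneModel) -> int:
    """Distance in bases between a region and a gene.

    0 when the region intersects the gene span; otherwise the minimum over
    transcripts of the distance from the region midpoint to the
    transcript's TSS or TTS point.
    """
    gs, ge = gene.span
    if overlap_length(region.start, region.end, gs, ge) > 0:
        return 0
    mid = region.midpoint
    return min(
        min(abs(mid - t.tss_point), abs(mid - t.tts_point))
        for t in gene.transcripts
    )


class GeneIndex:
    """Per-chromosome interval index over gene spans padded by ``q``.

    Area decompositions are computed once per transcript at build time, so
    repeated region queries reuse them.
    """

    def __init__(self, genes: Iterable[GeneModel], config: MatchConfig) -> None:
        self.config = config
        self._trees: dict[str, IntervalTree] = {}
        self._areas: dict[tuple[str, str], list[AreaInterval]] = {}
        self.genes = list(genes)
        pad = config.q
        for gene in self.genes:
            gs, ge = gene.span
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            tree.addi(gs - pad, ge + pad + 1, gene)
            for tr in gene.transcripts:
                self._areas[(gene.gene_id, tr.transcript_id)] = compute_areas(
                    tr, gene.span, config
                )

    @property
    def chromosomes(self) -> set[str]:
        return set(self._trees)

    def candidates(self, region: GenomicRegion) -> list[GeneModel]:
        """Genes whose padded span intersects the region, in index order."""
        tree = self._trees.get(region.chrom)
        if tree is None:
            return []
        hits = tree.overlap(region.start, region.end + 1)
        return sorted((h.data for h in hits), key=lambda g: (g.span, g.gene_id))

    def areas(self, gene: GeneModel, transcript_id: str) -> list[AreaInterval]:
        return self._areas[(gene.gene_id, transcript_id)]


def _row_sort_key(config: MatchConfig):
    def key(a: Association):
        return (a.gene_id, a.transcript_field, a.exon_index, config.priority_rank(a.area))

    return key


def match_region(
    region: GenomicRegion,
    genes: "GeneIndex | Iterable[GeneModel]",
    config: MatchConfig | None = None,
) -> list[Association]:
    """Exon-level associations of one region with its closest gene(s).

    Returns one row per overlapped area of every transcript of every gene
    at minimum distance (<= q), or an empty list when no gene qualifies.
    Rows are ordered by gene id, transcript id, exon index, then area
    priority.
    """
    if isinstance(genes, GeneIndex):
        index = genes
        if config is None:
            config = index.config
    else:
        if config is None:
            raise ValueError("config is required when genes is not a GeneIndex")
        index = GeneIndex(genes, config)

    per_gene: list[tuple[int, GeneModel, list[Association]]] = []
    for gene in index.candidates(region):
        distance = region_gene_distance(region, gene)
        if distance > config.q:
            continue
        rows: list[Association] = []
        for tr in gene.transcripts:
            for area in index.areas(gene, tr.transcript_id):
                ov = overlap_length(region.start, region.end, area.start, area.end)
                if ov == 0:
                    continue
                rows.append(
                    Association(
                        region_id=region.region_id,
                        midpoint=region.midpoint,
                        gene_id=gene.gene_id,
                        transcript_field=tr.transcript_id,
                        exon_index=area.exon_index,
                        area=area.label,
                        distance=distance,
                        perc_region=perc_region(ov, region.length),
                        perc_area=perc_area(ov, area),
                        extras=region.extra_columns,
                    )
                )
        if rows:
            per_gene.append((distance, gene, rows))

    if not per_gene:
        return []
    min_distance = min(d for d, _, _ in per_gene)
    out = [row for d, _, rows in per_gene if d == min_distance for row in rows]
    out.sort(key=_row_sort_key(config))
    return out


def annotate_regions(
    regions: Sequence[GenomicRegion],
    genes: "GeneIndex | Iterable[GeneModel]",
    config: MatchConfig | None = None,
) -> list[Association]:
    """Exon-level associations for many regions, in region input order."""
    if not isinstance(genes, GeneIndex):
        if config is None:
            raise ValueError("config is required when genes is not a GeneIndex")
        genes = GeneIndex(genes, config)
    out: list[Association] = []
    for region in regions:
        out.extend(match_region(region, genes, config))
    return out
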