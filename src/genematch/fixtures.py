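"""Deterministic test scenarios and a brute-force per-base oracle.

``worked_example`` emits a compact two-chromosome annotation exercising the
situations the matcher has to resolve: two overlapping genes with multiple
isoforms on opposite strands, and two quasi-overlapping genes whose TSS and
promoter areas both reach the same region. ``random_scenario`` generates
seeded random gene models and regions for property testing, and
``brute_force_annotate`` re-derives exon-level associations by labeling
every single base of a region — intentionally naive, as an independent
check on the interval arithmetic of the fast path.
"""

from __future__ import annotations

import random
from collections import Counter
from typing import Iterable

from .area_annotation import MatchConfig
from .association import _row_sort_key, region_gene_distance
from .genome_model import GeneModel, parse_gtf
from .region_io import Association, GenomicRegion

__all__ = [
    "worked_example",
    "random_scenario",
    "brute_force_annotate",
    "scenario_models",
]

_ORACLE_MAX_SPAN = 10**6


def worked_example() -> tuple[str, str]:
    """GTF and BED text for the canonical two-chromosome worked example.

    Chromosome 1 carries two overlapping genes on opposite strands (Gene1
    with two isoforms, Gene2 whose first exon is its rightmost one);
    chromosome 2 carries two quasi-overlapping genes whose upstream areas
    meet over the third region.
    """
    exons = [
        ("1", "Gene1", "Tr1_Gene1", "+", 3600, 5299),
        ("1", "Gene1", "Tr2_Gene1", "+", 3600, 5299),
        ("1", "Gene1", "Tr2_Gene1", "+", 6100, 6500),
        ("1", "Gene2", "Tr1_Gene2", "-", 2001, 3500),
        ("1", "Gene2", "Tr1_Gene2", "-", 5500, 6700),
        ("2", "Gene3", "Tr1_Gene3", "+", 2504, 2573),
        ("2", "Gene3", "Tr1_Gene3", "+", 3200, 3600),
        ("2", "Gene4", "Tr1_Gene4", "-", 2076, 2211),
    ]
    gtf = "".join(
        f'{c}\tfixture\texon\t{s}\t{e}\t.\t{st}\t.\t'
        f'gene_id "{g}"; transcript_id "{t}";\n'
        for c, g, t, st, s, e in exons
    )
    bed = "1\t3400\t3700\n1\t5900\t6250\n2\t2102\t2702\n"
    return gtf, bed


def random_scenario(
    seed: int, n_genes: int = 4, n_regions: int = 8
) -> tuple[str, str]:
    """Seeded random GTF + BED texts for property testing.

    Genes get 1-5 exons (50-1500 bp) separated by 50-2000 bp introns, on
    random strands across two chromosomes, with 1-2 isoforms sharing the
    gene locus. Consecutive genes are placed so that some pairs overlap,
    some quasi-overlap (gaps shorter than the default flank widths) and the
    rest are well separated. Regions (50-1000 bp) are placed uniformly over
    the covered span. Identical seeds give identical texts.
    """
    if n_genes < 1 or n_regions < 1:
        raise ValueError("n_genes and n_regions must be >= 1")
    rng = random.Random(seed)
    gtf_lines: list[str] = []
    max_coord: dict[str, int] = {}
    cursor: dict[str, int] = {}
    for i in range(n_genes):
        chrom = rng.choice(("chrA", "chrB"))
        strand = rng.choice("+-")
        prev_end = cursor.get(chrom, 1000)
        placement = rng.random()
        if placement < 0.25 and chrom in cursor:
            start = max(1, prev_end - rng.randint(200, 2000))  # overlapping pair
        elif placement < 0.45:
            start = prev_end + rng.randint(50, 1400)  # quasi-overlapping
        else:
            start = prev_end + rng.randint(2000, 12000)
        gene_id = f"G{i + 1}"
        gene_end = start
        for k in range(rng.randint(1, 2)):
            transcript_id = f"T{k + 1}_{gene_id}"
            pos = start + rng.randint(0, 300)
            for _ in range(rng.randint(1, 5)):
                exon_end = pos + rng.randint(50, 1500) - 1
                gtf_lines.append(
                    f'{chrom}\tsim\texon\t{pos}\t{exon_end}\t.\t{strand}\t.\t'
                    f'gene_id "{gene_id}"; transcript_id "{transcript_id}";\n'
                )
                gene_end = max(gene_end, exon_end)
                pos = exon_end + 1 + rng.randint(50, 2000)
        cursor[chrom] = gene_end
        max_coord[chrom] = max(max_coord.get(chrom, 0), gene_end)
    bed_lines = []
    chroms = sorted(max_coord)
    for _ in range(n_regions):
        chrom = rng.choice(chroms)
        start = rng.randint(1, max_coord[chrom] + 5000)
        end = start + rng.randint(50, 1000) - 1
        bed_lines.append(f"{chrom}\t{start}\t{end}\n")
    return "".join(gtf_lines), "".join(bed_lines)


def brute_force_annotate(
    region: GenomicRegion,
    genes: Iterable[GeneModel],
    config: MatchConfig,
) -> list[Association]:
    """Exon-level associations derived by labeling every base of the region.

    For each transcript, every base of the region is tested for membership
    in each area interval and counted; overlaps, PercRegion and PercArea
    follow from the counts. The closest-gene filter is applied by
    exhaustively evaluating the distance of every gene. Refuses scenarios
    whose coordinates exceed 10^6 (the oracle is intentionally naive).
    """
    from .area_annotation import compute_areas  # local to keep module load light

    genes = list(genes)
    top = max(
        [region.end] + [g.span[1] + config.q for g in genes if g.chrom == region.chrom],
        default=region.end,
    )
    if top > _ORACLE_MAX_SPAN:
        raise ValueError(f"scenario span {top} exceeds oracle limit {_ORACLE_MAX_SPAN}")

    per_gene: list[tuple[int, list[Association]]] = []
    for gene in sorted(
        (g for g in genes if g.chrom == region.chrom),
        key=lambda g: (g.span, g.gene_id),
    ):
        distance = region_gene_distance(region, gene)
        if distance > config.q:
            continue
        rows: list[Association] = []
        for tr in gene.transcripts:
            areas = compute_areas(tr, gene.span, config)
            counts: Counter[int] = Counter()
            for base in range(region.start, region.end + 1):
                for j, area in enumerate(areas):
                    if area.start <= base <= area.end:
                        counts[j] += 1
                        break  # areas of one transcript are disjoint
            for j, n_bases in sorted(counts.items()):
                area = areas[j]
                pa = -1.0 if area.denom_length is None else 100.0 * n_bases / area.denom_length
                rows.append(
                    Association(
                        region_id=region.region_id,
                        midpoint=region.midpoint,
                        gene_id=gene.gene_id,
                        transcript_field=tr.transcript_id,
                        exon_index=area.exon_index,
                        area=area.label,
                        distance=distance,
                        perc_region=100.0 * n_bases / region.length,
                        perc_area=pa,
                        extras=region.extra_columns,
                    )
                )
        if rows:
            per_gene.append((distance, rows))

    if not per_gene:
        return []
    min_distance = min(d for d, _ in per_gene)
    out = [r for d, rows in per_gene if d == min_distance for r in rows]
    out.sort(key=_row_sort_key(config))
    return out


def scenario_models(gtf_text: str) -> list[GeneModel]:
    """Convenience: parse a scenario's GTF text into gene models."""
    return parse_gtf(gtf_text.splitlines())
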