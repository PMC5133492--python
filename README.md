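# genematch

Associate genomic regions with their closest gene(s) and annotate each
association with the gene area it overlaps.

Sequencing assays of chromatin features — transcription-factor binding
(ChIP-seq), DNA methylation (Methyl-seq), chromatin accessibility
(DNase-seq, ATAC-seq) — yield sets of genomic intervals that only become
biologically interpretable once they are tied to nearby genes, and *where*
on a gene a region falls (promoter, first exon, an intron, downstream, ...)
changes what it is likely to mean. `genematch` takes a GTF annotation and a
BED file of regions and reports, for every region, the closest gene(s) and
the area(s) of the gene the region overlaps, at a choice of three
aggregation levels. It works for any organism with a GTF annotation, and it
reports *all* closest genes when several tie (overlapping genes, or
"quasi-overlapping" genes whose upstream areas both reach the region).

## The model

Each transcript's neighborhood is decomposed into eight disjoint areas
(widths configurable, defaults in parentheses):

| Area | Definition |
|---|---|
| `TSS` | intergenic window of width *t* (200 bp) immediately upstream of the transcription start site |
| `PROMOTER` | intergenic window of width *p* (1300 bp) upstream of the TSS area |
| `UPSTREAM` | remaining intergenic space upstream, out to the maximum distance *q* (10 kbp) |
| `1st_EXON` | the whole first exon |
| `INTRON` | each gap between consecutive exons |
| `GENE_BODY` | each exon other than the first |
| `TTS` | intergenic window of width *s* (0 bp, absent by default) downstream of the transcription termination site |
| `DOWNSTREAM` | remaining intergenic space downstream, out to *q* |

On the minus strand the layout is mirrored; exon 1 is always the 5′-most
exon. A region is matched to the gene(s) minimizing the distance from its
midpoint to any transcript's TSS/TTS point (0 if it overlaps the gene), ties
kept. Each association carries **PercRegion** (percent of the region inside
the area) and **PercArea** (percent of the area covered by the region; −1
for areas without a fixed length).

At **exon** level every overlapped area is reported. At **transcript**
level one area is chosen per region × transcript: the area with
PercRegion ≥ *w* (50 %), else the area with PercArea ≥ *v* (90 %), highest
PercRegion first, remaining ties broken by a configurable priority ranking
(default `TSS, 1st_EXON, PROMOTER, TTS, INTRON, GENE_BODY, UPSTREAM,
DOWNSTREAM`). At **gene** level the per-transcript winners compete by
priority; transcripts tying on the same area are comma-joined into one row
with exon number −1.

## Worked example

The package ships a generator for a small two-chromosome scenario: two
overlapping genes on opposite strands (Gene1 with two isoforms; Gene2 whose
first exon is its rightmost), and two quasi-overlapping genes whose TSS and
promoter areas meet over the same region.

```sh
python -c "
from genematch.fixtures import worked_example
gtf, bed = worked_example()
open('ann.gtf','w').write(gtf); open('reg.bed','w').write(bed)"
genematch ann.gtf reg.bed out.tsv --report gene
cat out.tsv
```

prints

```
Region	Midpoint	Gene	Transcript	Exon	Area	Distance	PercRegion	PercArea
1_3400_3700	3550	Gene1	Tr1_Gene1,Tr2_Gene1	-1	TSS	0	66.45	100.00
1_3400_3700	3550	Gene2	Tr1_Gene2	2	INTRON	0	66.45	-1
1_5900_6250	6075	Gene1	Tr2_Gene1	2	INTRON	0	56.98	-1
1_5900_6250	6075	Gene2	Tr1_Gene2	1	1st_EXON	0	100.00	29.23
2_2102_2702	2402	Gene3	Tr1_Gene3	1	TSS	0	33.28	100.00
2_2102_2702	2402	Gene4	Tr1_Gene4	1	TSS	0	33.28	100.00
```

Reading the first row: region `1_3400_3700` overlaps both genes; for Gene1
it covers the entire TSS window (PercArea 100.00) and that window holds
66.45 % of the region's bases, which exceeds the 50 % rule threshold, so
both isoforms resolve to `TSS` and are comma-joined with exon −1. The last
two rows are the quasi-overlapping pair: neither gene's areas hold half the
region, so the PercArea ≥ 90 % rule applies and TSS (fully covered, highest
PercRegion) wins for both. Distance 0 throughout because every region
overlaps its gene(s). Running with `--report exon` instead prints all 16
region × area rows; `--report transcript` one row per isoform. Extra BED
columns beyond the first three are passed through after `PercArea`.

The same pipeline is available as a library:

```python
from genematch import MatchConfig, parse_gtf, parse_bed, annotate_regions

genes = parse_gtf(open("ann.gtf"))
regions = parse_bed(open("reg.bed"))
rows = annotate_regions(regions, genes, MatchConfig())
```

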