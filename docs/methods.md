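# Methods

## Coordinate conventions

All arithmetic is done on 1-based inclusive intervals. GTF coordinates are
already 1-based inclusive and are kept verbatim. BED coordinates are also
taken verbatim — no 0-based/half-open conversion is applied — and region
length is defined as `end − start + 1`. This inclusive interpretation is a
deliberate contract of the package: all overlap percentages and the shipped
worked example are defined on it, and callers whose BED files follow the
strict UCSC half-open convention should be aware that every region is
treated as one base longer on the left than the half-open reading would
give. The region identifier is `chrom_start_end` and the midpoint is
`floor((start+end)/2)` (the floor only matters for odd sums; any convention
agrees on even ones).

## Gene model

Only `exon` feature lines of the GTF are consumed: the area decomposition
needs nothing else, and `gene`/`transcript`/`CDS` lines are redundant with
(or unrelated to) exon structure. Exons of one transcript must be pairwise
disjoint — the intron definition ("the gap between consecutive exons")
collapses otherwise — and overlapping exons are rejected as malformed.
Exons are numbered in transcript (5′→3′) order, so exon 1 is the leftmost
exon on the plus strand and the rightmost on the minus strand. The gene
span is the interval from the first to the last exonic base over all
isoforms. Chromosome names are matched as exact strings between GTF and
BED; no `chr`-prefix normalization is attempted, because silent coercion
hides annotation mismatches — the CLI instead warns and lists BED
chromosomes absent from the annotation.

## Area decomposition

Per transcript, `1st_EXON`, `GENE_BODY` (each later exon) and `INTRON`
(each inter-exon gap) tile the transcript span exactly. The five intergenic
areas extend away from the TSS point (`TSS` width *t*, then `PROMOTER`
width *p*, then `UPSTREAM` out to the maximum association distance *q*) and
from the TTS point (`TTS` width *s*, then `DOWNSTREAM` out to *q*),
mirrored on the minus strand. Zero-width areas are omitted (with the
default *s* = 0 there is no TTS area). Coordinates are clipped at 1.

Intergenic areas are intersected with the complement of the transcript's
**own** gene span; other genes never mask areas. This choice is pinned by
two behaviors the package guarantees together: a promoter/TSS window may
overlap a neighboring gene's exons and still be reported (quasi-overlapping
genes), while a short isoform of a long gene contributes no DOWNSTREAM area
inside its own gene's span (the flank starts only past the span).

Exon-index bookkeeping for the report: TSS/PROMOTER/UPSTREAM rows carry
exon 1, TTS/DOWNSTREAM rows carry the last exon's index, GENE_BODY rows the
overlapped exon's index, and INTRON rows the index of the exon that follows
the intron in transcript order (the intron before exon *k* is intron row
*k*).

## Percentages and distance

`PercRegion` = 100 × overlap / region length. `PercArea` = 100 × overlap /
area length for areas with a well-defined length: exon length for
`1st_EXON`/`GENE_BODY`, and the **configured nominal width** *t*/*p*/*s*
for `TSS`/`PROMOTER`/`TTS` even when the realized interval was clipped by
the gene span or by coordinate 1 (the nominal width is the biologically
meaningful denominator; clipping is bookkeeping). `INTRON`, `UPSTREAM` and
`DOWNSTREAM` have no fixed length — intron lengths vary per gene and the
flank extents depend on *q* — so their PercArea is the sentinel −1.

Distance is 0 whenever the region intersects the gene span, else the
minimum over transcripts of the midpoint-to-TSS/TTS point distance,
reported unsigned. Candidate genes must lie within *q* (inclusive
comparison: `distance ≤ q`) and contribute at least one overlapped area;
only the minimum-distance gene(s) are kept, all of them on ties — which is
exactly how overlapping and quasi-overlapping genes end up co-reported with
distance 0. A region matching no gene within *q* produces no output rows
rather than a placeholder row. When a region overlaps one gene and also
falls in a non-overlapping neighbor's flank, the closest-gene rule keeps
only the overlapping gene.

## Selection rules

Per region × transcript, on **unrounded** percentages:

1. areas with PercRegion ≥ *w* (default 50): pick the highest PercRegion,
   ties by the priority ranking;
2. otherwise areas with PercArea ≥ *v* (default 90; the −1 sentinel never
   qualifies): highest PercRegion, ties by priorities;
3. otherwise — a branch that can only arise when a region's overlap is
   spread thinly across areas — fall back to the highest PercRegion over
   all areas, ties by priorities. This fallback is the most continuous
   extension of rule 2's tie-break and guarantees the transcript- and
   gene-level reports always emit exactly one row per group.

Both thresholds compare with ≥. Applying them to unrounded values avoids
artifacts where a value printing as exactly 50.00 sits on the wrong side of
the threshold.

At gene level, per-transcript winners compete by priority rank. A single
winner is emitted verbatim. Tied transcripts (same winning area) are merged
into one row: transcript IDs comma-joined in input order, exon number −1,
and PercRegion/PercArea taken from the tied transcript with maximal
PercRegion (a maximum, not an average: it keeps the row equal to one real
transcript row; when the tied values are identical, as for identical
first exons, the choice is invisible).

## Output

Tab-separated with one header line (`Region, Midpoint, Gene, Transcript,
Exon, Area, Distance, PercRegion, PercArea`); BED columns beyond the third
are appended after PercArea in input order. Percentages are printed with
exactly two decimals, rounded half away from zero at output time only; −1
prints literally. Row order is deterministic: region input order, then gene
ID, transcript ID, exon number, and area priority. Reruns on identical
inputs are byte-identical.

## Synthetic scenarios and the oracle

`fixtures.worked_example()` emits a compact hand-constructed scenario
covering the hard cases: overlapping genes on opposite strands, a
multi-isoform gene, a minus-strand gene whose exon 1 is its rightmost exon,
and a quasi-overlapping gene pair whose flank areas meet over one region.
Its coordinates were chosen so every percentage in the report is a
round-trippable fraction (e.g. 200/301 → 66.45); one GENE_BODY denominator
is ambiguous at two-decimal precision (1500 and 1501 both print 6.73) and
the generator pins 1500.

`fixtures.random_scenario(seed, ...)` generates seeded gene models (1–5
exons of 50–1500 bp, introns 50–2000 bp, 1–2 isoforms, mixed strands on two
chromosomes) placed so that some consecutive pairs overlap, some
quasi-overlap (gaps shorter than the default flank widths) and the rest are
separated, plus regions of 50–1000 bp placed uniformly over the covered
span. These sizes are typical of compact annotations and peak calls; the
generator does not emulate real peak-width or signal distributions,
chromosome-scale gene density, or annotation pathologies (trans-spliced or
multi-strand genes), so passing tests demonstrate algorithmic correctness
of the interval logic, not robustness to every real-world GTF.

`fixtures.brute_force_annotate` is the independent check on the matcher: it
labels every single base of a region against every area interval and counts
labels, derives all percentages from the counts, and applies the
closest-gene filter by exhaustively evaluating every gene's distance. It
deliberately shares only the area decomposition with the fast path and
refuses scenarios spanning more than 10⁶ bp. The test suite and the
acceptance script require exact agreement between the two paths across
seeded scenario sweeps at all three aggregation levels.

## Problem sizes

The shipped verification runs at desk scale: the worked example (4 genes, 5
transcripts, 3 regions) and sweeps of 50 random scenarios with 4 genes and
5 regions each, which complete in seconds while exercising every rule
branch. The matcher itself indexes gene spans (padded by *q*) in per-
chromosome interval trees and precomputes area decompositions once per
transcript, so genome-scale annotations with 10⁵–10⁶ regions are handled
in memory proportional to the annotation.

## Known limitations

- BED input is interpreted inclusively (see above); strict half-open BED
  semantics differ by one base.
- UTR/CDS structure is not modeled; `GENE_BODY` is exonic sequence only and
  introns are never subdivided.
- GFF3 is not parsed; only the GTF attribute dialect (`key "value";`) is
  supported.
- Distal, enhancer-style multi-gene assignment (basal-plus-extension
  regulatory domains) is out of scope: associations are strictly
  closest-gene within *q*.
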