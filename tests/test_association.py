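"""Exon-level matching: overlaps, percentages, distance, closest-gene filter."""

import pytest

from genematch import (
    GeneIndex,
    GenomicRegion,
    MatchConfig,
    match_region,
    overlap_length,
    perc_area,
    perc_region,
    region_gene_distance,
)
from genematch.area_annotation import AreaInterval
from genematch.fixtures import brute_force_annotate, random_scenario, scenario_models
from genematch.region_io import parse_bed
from conftest import gene


class TestOverlapLength:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((3400, 3700), (3400, 3599), 200),
            ((1, 10), (20, 30), 0),
            ((5, 5), (5, 5), 1),
            ((10, 20), (20, 30), 1),
        ],
    )
    def test_inclusive_interval_overlap(self, a, b, expected):
        assert overlap_length(*a, *b) == expected
        assert overlap_length(*b, *a) == expected


class TestPercentages:
    @pytest.mark.parametrize(
        "overlap, length, expected",
        [(200, 301, 66.45), (351, 351, 100.0), (129, 601, 21.46)],
    )
    def test_perc_region_matches_reported_values(self, overlap, length, expected):
        assert round(perc_region(overlap, length), 2) == expected

    def test_perc_area_fixed_length_area(self):
        area = AreaInterval("1st_EXON", 3600, 5299, 1, 1700)
        assert round(perc_area(101, area), 2) == 5.94
        assert perc_area(1700, area) == 100.0

    def test_perc_area_undefined_for_variable_length_areas(self):
        intron = AreaInterval("INTRON", 3501, 5499, 2, None)
        assert perc_area(123, intron) == -1.0


class TestRegionGeneDistance:
    def test_overlap_means_zero(self, example_genes):
        region = GenomicRegion("2", 2102, 2702)
        assert region_gene_distance(region, gene(example_genes, "Gene4")) == 0

    def test_midpoint_to_tss(self):
        genes = scenario_models(
            'c\ts\texon\t400\t900\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
        )
        assert region_gene_distance(GenomicRegion("c", 100, 200), genes[0]) == 250

    def test_minimum_over_tss_and_tts_points(self):
        gtf = (
            'c\ts\texon\t400\t450\t.\t+\t.\tgene_id "G"; transcript_id "T1";\n'
            'c\ts\texon\t290\t310\t.\t+\t.\tgene_id "G"; transcript_id "T2";\n'
        )
        genes = scenario_models(gtf)
        # midpoint 150; candidate points: T1 TSS 400 (250), T1 TTS 450 (300),
        # T2 TSS 290 (140), T2 TTS 310 (160) -> minimum 140
        assert region_gene_distance(GenomicRegion("c", 100, 200), genes[0]) == 140


class TestMatchRegion:
    def test_overlapping_genes_all_reported(self, example_genes, default_config):
        region = parse_bed(["1\t3400\t3700"])[0]
        rows = match_region(region, example_genes, default_config)
        assert len(rows) == 6
        triples = [(r.gene_id, r.transcript_field, r.area) for r in rows]
        assert triples == [
            ("Gene1", "Tr1_Gene1", "TSS"),
            ("Gene1", "Tr1_Gene1", "1st_EXON"),
            ("Gene1", "Tr2_Gene1", "TSS"),
            ("Gene1", "Tr2_Gene1", "1st_EXON"),
            ("Gene2", "Tr1_Gene2", "INTRON"),
            ("Gene2", "Tr1_Gene2", "GENE_BODY"),
        ]
        assert all(r.distance == 0 for r in rows)

    def test_quasi_overlapping_perc_region_sums_to_100(
        self, example_genes, default_config
    ):
        region = parse_bed(["2\t2102\t2702"])[0]
        rows = match_region(region, example_genes, default_config)
        assert len(rows) == 7
        by_gene = {}
        for r in rows:
            by_gene.setdefault(r.gene_id, []).append(r.perc_region)
        assert set(by_gene) == {"Gene3", "Gene4"}
        for values in by_gene.values():
            assert round(sum(values), 2) == 100.00

    def test_unknown_chromosome_yields_no_rows(self, example_genes, default_config):
        region = GenomicRegion("chrUn", 100, 200)
        assert match_region(region, example_genes, default_config) == []

    def test_region_beyond_q_yields_no_rows(self, example_genes, default_config):
        region = GenomicRegion("1", 50_000, 50_400)
        assert match_region(region, example_genes, default_config) == []

    def test_only_minimum_distance_genes_kept(self):
        gtf = (
            'c\ts\texon\t5000\t6000\t.\t+\t.\tgene_id "NEAR"; transcript_id "Tn";\n'
            'c\ts\texon\t9000\t9500\t.\t+\t.\tgene_id "FAR"; transcript_id "Tf";\n'
        )
        genes = scenario_models(gtf)
        cfg = MatchConfig()
        # region overlaps NEAR (distance 0) and lies in FAR's upstream flank
        rows = match_region(GenomicRegion("c", 5500, 5600), genes, cfg)
        assert {r.gene_id for r in rows} == {"NEAR"}

    def test_distance_is_gene_level_and_uniform(self, example_exon_rows):
        by_gene_region = {}
        for r in example_exon_rows:
            by_gene_region.setdefault((r.region_id, r.gene_id), set()).add(r.distance)
        assert all(len(d) == 1 for d in by_gene_region.values())

    def test_extras_propagated_to_rows(self, example_genes, default_config):
        region = parse_bed(["1\t3400\t3700\tpeakA\t87"])[0]
        rows = match_region(region, example_genes, default_config)
        assert all(r.extras == ("peakA", "87") for r in rows)


class TestOracleEquivalence:
    def test_worked_example_matches_brute_force(self, example_genes, default_config):
        index = GeneIndex(example_genes, default_config)
        for bed_line in ("1\t3400\t3700", "1\t5900\t6250", "2\t2102\t2702"):
            region = parse_bed([bed_line])[0]
            assert match_region(region, index) == brute_force_annotate(
                region, example_genes, default_config
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_random_scenarios_match_brute_force(self, seed, default_config):
        gtf, bed = random_scenario(seed, n_genes=4, n_regions=6)
        genes = scenario_models(gtf)
        index = GeneIndex(genes, default_config)
        for region in parse_bed(bed.splitlines()):
            assert match_region(region, index) == brute_force_annotate(
                region, genes, default_config
            )


class TestProperties:
    def test_per_transcript_perc_region_conservation(self, default_config):
        # a region entirely inside a transcript's area union has PercRegion
        # values summing to 100 per transcript
        for seed in range(8):
            gtf, bed = random_scenario(seed, n_genes=3, n_regions=5)
            genes = scenario_models(gtf)
            index = GeneIndex(genes, default_config)
            for region in parse_bed(bed.splitlines()):
                rows = match_region(region, index)
                per_tr = {}
                for r in rows:
                    per_tr.setdefault((r.gene_id, r.transcript_field), 0.0)
                    per_tr[(r.gene_id, r.transcript_field)] += r.perc_region
                for (gene_id, tr_id), total in per_tr.items():
                    g = next(g for g in genes if g.gene_id == gene_id)
                    tr = next(
                        t for t in g.transcripts if t.transcript_id == tr_id
                    )
                    areas = index.areas(g, tr_id)
                    covered = sum(
                        overlap_length(region.start, region.end, a.start, a.end)
                        for a in areas
                    )
                    if covered == region.length:
                        assert total == pytest.approx(100.0, abs=0.01)

    def test_q_monotonicity(self, default_config):
        small = default_config
        large = MatchConfig(q=40_000)
        for seed in range(8):
            gtf, bed = random_scenario(seed, n_genes=3, n_regions=5)
            genes = scenario_models(gtf)
            for region in parse_bed(bed.splitlines()):
                rows_small = match_region(region, genes, small)
                rows_large = match_region(region, genes, large)
                if not rows_small:
                    continue
                if rows_small[0].distance == 0:
                    # distance-0 associations are unaffected by enlarging q
                    zero_small = [r for r in rows_small if r.distance == 0]
                    zero_large = [r for r in rows_large if r.distance == 0]
                    assert zero_small == zero_large
                else:
                    # the closest gene set is unchanged, though its areas may
                    # extend further under the larger q
                    assert {r.gene_id for r in rows_small} <= {
                        r.gene_id for r in rows_large
                    } or rows_large[0].distance < rows_small[0].distance
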