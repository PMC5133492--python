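import pytest

from genematch import GeneIndex, MatchConfig, annotate_regions, parse_bed, parse_gtf
from genematch.fixtures import worked_example


@pytest.fixture(scope="session")
def example_texts():
    return worked_example()


@pytest.fixture(scope="session")
def example_genes(example_texts):
    gtf, _ = example_texts
    return parse_gtf(gtf.splitlines())


@pytest.fixture(scope="session")
def example_regions(example_texts):
    _, bed = example_texts
    return parse_bed(bed.splitlines())


@pytest.fixture(scope="session")
def default_config():
    return MatchConfig()


@pytest.fixture(scope="session")
def example_exon_rows(example_genes, example_regions, default_config):
    index = GeneIndex(example_genes, default_config)
    return annotate_regions(example_regions, index)


def gene(genes, gene_id):
    return next(g for g in genes if g.gene_id == gene_id)


def transcript(genes, transcript_id):
    for g in genes:
        for t in g.transcripts:
            if t.transcript_id == transcript_id:
                return t
    raise KeyError(transcript_id)
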