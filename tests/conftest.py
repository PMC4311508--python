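import pytest

from lncskin.core import GeneModel, GenomicInterval, ReferenceAnnotation
from lncskin.synthetic_data import FixtureConfig, generate_fixture


@pytest.fixture(scope="session")
def default_config():
    return FixtureConfig(seed=1)


@pytest.fixture(scope="session")
def fixture_bundle(default_config):
    """One fully generated synthetic study, shared across the suite."""
    return generate_fixture(default_config)


@pytest.fixture(scope="session")
def truth(fixture_bundle):
    """Ground-truth sidecar indexed by transcript id."""
    return fixture_bundle.assemblies.truth.set_index("transcript_id")


def make_gene(gid, chrom, pairs, strand="+", biotype="protein_coding"):
    exons = tuple(GenomicInterval(chrom, a, b, strand) for a, b in pairs)
    return GeneModel(gid, biotype, strand, exons)


@pytest.fixture()
def toy_reference():
    """Hand-built reference: a coding gene with a large intron, a lincRNA,
    and an antisense partner overlapping the coding gene's first exon."""
    genes = [
        make_gene("gene_cod", "chr1", [(1000, 1200), (9000, 9200)], "+"),
        make_gene("gene_lnc", "chr1", [(20000, 20500), (21500, 22000)], "-",
                  biotype="lincRNA"),
        make_gene("gene_as", "chr1", [(1100, 1700)], "-", biotype="antisense"),
    ]
    return ReferenceAnnotation(genes)
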