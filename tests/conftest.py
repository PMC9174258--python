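import pytest

from ncburden import fixtures
from ncburden.gene_catalog import GeneCatalog
from ncburden.genome_io import GeneFeature
from ncburden.mutsig import CohortDesign


@pytest.fixture(scope="session")
def fixture_spec():
    return fixtures.spike_demo(seed=17)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, fixture_spec):
    """The standard spiked synthetic dataset, generated once per session."""
    outdir = tmp_path_factory.mktemp("fx")
    fixtures.generate(fixture_spec, outdir)
    return outdir


@pytest.fixture(scope="session")
def manifest(fixture_dir):
    import json

    with open(fixture_dir / "manifest.json") as fh:
        return json.load(fh)


@pytest.fixture
def small_design():
    """5 case + 5 control samples; matches the hand-computable examples."""
    cohort = {f"C{i}": "breast" for i in range(5)}
    cohort.update({f"X{i}": "other" for i in range(5)})
    return CohortDesign("breast", cohort)


@pytest.fixture
def toy_gene():
    return GeneFeature("G1", "G1", "chr1", 0, 100)


def make_catalog(rows, sources=None):
    """rows: (gene_id, chrom, start, end) or full GeneFeature tuples."""
    genes = []
    for row in rows:
        if len(row) == 4:
            gid, chrom, s, e = row
            genes.append(GeneFeature(gid, gid, chrom, s, e))
        else:
            genes.append(GeneFeature(*row))
    return GeneCatalog(genes=genes, source_priority=sources or ["test"])
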