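import pytest

from spliceoform.gene_models import DEFAULT_FLANK, enumerate_junctions
from spliceoform.synthetic_data import FixtureSpec, build_fixture


@pytest.fixture(scope="session")
def fixture():
    """Default synthetic genome: Dmrt1 + 2 paralogs + normalizer, seed 0."""
    return build_fixture(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def dmrt1(fixture):
    return fixture.gene("Dmrt1")


@pytest.fixture(scope="session")
def junction_library(fixture):
    dmrt = [g for g in fixture.genes if g.family_id == "Dmrt"]
    return enumerate_junctions(dmrt, DEFAULT_FLANK, fixture.genome)


@pytest.fixture(scope="session")
def gene_regions(fixture):
    return {
        g.gene_id: g.span.extract(fixture.genome)
        for g in fixture.genes
        if g.family_id == "Dmrt"
    }
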