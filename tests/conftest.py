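import pytest

from raidesign.config import RuleConfig
from raidesign.rai_registry import builtin_cassettes
from raidesign.splice_scoring import build_default_pwms
from raidesign.synthetic_fixtures import FixtureSpec, Planted, make_toy_gene
from raidesign.transcript_model import write_fasta, write_gff3


@pytest.fixture(scope="session")
def cassettes():
    return builtin_cassettes()


@pytest.fixture(scope="session")
def scon(cassettes):
    return cassettes["SCON-loxP"]


@pytest.fixture(scope="session")
def decai(cassettes):
    return cassettes["DECAI"]


@pytest.fixture(scope="session")
def config():
    return RuleConfig()


@pytest.fixture(scope="session")
def pwms():
    return build_default_pwms()


@pytest.fixture(scope="session")
def toy():
    """Default 3-exon toy gene with one planted MAG-R gap in exon 2."""
    spec = FixtureSpec(seed=1, planted=(Planted("mag_r_site", 1, 180),),
                       clean_zones=(1,))
    return make_toy_gene(spec)


@pytest.fixture(scope="session")
def toy_files(toy, tmp_path_factory):
    gene, genome = toy
    d = tmp_path_factory.mktemp("toyfiles")
    write_gff3(gene, d / "toy.gff3")
    write_fasta({genome.contig_id: genome}, d / "toy.fasta")
    return d / "toy.gff3", d / "toy.fasta"
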