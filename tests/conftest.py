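import pytest

from hedscape.grantham import default_model
from hedscape.hla import HlaGenotype, parse_allele
from hedscape.synthetic import fixture_sequences


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def dictionary():
    """The deterministic fixture allele pool (8 alleles per scored locus)."""
    return fixture_sequences()


def make_genotype(subject_id="S1", **pairs):
    """Genotype from locus= (name1, name2) keyword pairs; defaults to the
    first two fixture alleles at every scored locus."""
    defaults = {
        locus: (f"{locus}*01:01", f"{locus}*02:01")
        for locus in ("A", "B", "C", "DRB1", "DQB1", "DPB1")
    }
    defaults.update(pairs)
    return HlaGenotype(
        subject_id=subject_id,
        alleles={
            locus: tuple(parse_allele(n) for n in names)
            for locus, names in defaults.items()
        },
    )


@pytest.fixture
def genotype():
    return make_genotype()
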