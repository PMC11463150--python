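import pytest

from dopascore.genotype import DEFAULT_LOCI, parse_genotype


@pytest.fixture(scope="session")
def loci():
    return DEFAULT_LOCI


@pytest.fixture(scope="session")
def make_call():
    """Build a canonical call from (rsid, text)."""

    def _make(rsid, text):
        return parse_genotype(text, DEFAULT_LOCI[rsid])

    return _make
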