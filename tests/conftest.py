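import pytest

from mimircraft import load_fixtures
from mimircraft.verify import decode_all


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def designs():
    """All packaged hairpin templates decoded (mimiRs annotated against the
    mCherry reporter, negative control in generic fold mode)."""
    return decode_all()


@pytest.fixture(scope="session")
def mcherry(fixtures):
    return fixtures["mcherry_mrna_nematostella_zebrafish"]
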