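import pytest

from fragile_rss import load_fixture_oligos, load_fixture_sequences


@pytest.fixture(scope="session")
def oligos():
    return load_fixture_oligos()


@pytest.fixture(scope="session")
def sequences():
    return load_fixture_sequences()
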