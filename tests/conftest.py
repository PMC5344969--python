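import pytest

from gistmax import default_panel, fixture_cohort, load_max_transcript


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def transcript():
    return load_max_transcript()


@pytest.fixture(scope="session")
def cohort():
    return fixture_cohort()


@pytest.fixture
def max_exon12_indices(panel):
    """Order indices of the MAX exon 1-2 amplicons (the GIST48 deletion)."""
    return [a.index for a in panel if a.gene == "MAX" and a.exon in ("exon1", "exon2")]
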