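import pytest
from hypothesis import settings

from scoscreen import datasets

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def table5_profiles():
    """Published YPGlc fatty-acid profiles keyed by strain id."""
    return {p.strain_id: p for p in datasets.load_fatty_acid_profiles()}


@pytest.fixture(scope="session")
def table4_wide():
    """Published culture endpoint table (wide layout)."""
    return datasets.load_culture_endpoints()


@pytest.fixture(scope="session")
def its_sequences():
    """Partial ITS amplicon sequences keyed by record id."""
    return {s.id: s for s in datasets.load_its_sequences()}


@pytest.fixture(scope="session")
def reference_patterns():
    """Gel-derived reference digest patterns."""
    return datasets.load_reference_patterns()
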