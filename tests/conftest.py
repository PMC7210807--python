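import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_tables():
    """Count-backed allele-frequency tables of the packaged reference panel,
    in panel order."""
    from strpanel import reference_panel_tables

    return reference_panel_tables()


@pytest.fixture(scope="session")
def reference_loci():
    from strpanel import load_reference_loci

    return load_reference_loci()
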