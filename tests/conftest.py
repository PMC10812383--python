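import pytest
from hypothesis import HealthCheck, settings

import polestrat as ps

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return ps.load_default_driver_catalog()


@pytest.fixture(scope="session")
def domain_map():
    return ps.load_default_domain_map()


@pytest.fixture(scope="session")
def signatures():
    return ps.load_default_signatures()


@pytest.fixture(scope="session")
def context_sets(signatures):
    return [
        ps.build_context_set(signatures[s])
        for s in ("SBS10a", "SBS10b", "SBS14", "SBS28")
    ]


@pytest.fixture(scope="session")
def transcript():
    return ps.load_default_transcript()


@pytest.fixture(scope="session")
def channel_index(transcript):
    from polestrat.simulate import transcript_channel_index

    return transcript_channel_index(transcript)


@pytest.fixture(scope="session")
def small_cohort(catalog):
    """A small deterministic synthetic cohort shared across tests."""
    config = ps.default_config(11, catalog)
    return ps.simulate_cohort(config, catalog=catalog)
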