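import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study():
    """The embedded pneumonia case-study configuration."""
    from bayesgains import paper_fixture

    return paper_fixture()
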