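import pytest
from hypothesis import HealthCheck, settings

from pestbudget import iowa_2018

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def config():
    """The bundled 2018 Iowa case-study configuration."""
    return iowa_2018()
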