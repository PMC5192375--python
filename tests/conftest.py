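import logging

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Rate-rule warnings are expected noise in scans that deliberately violate it.
logging.getLogger("terma.core").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def standard_records():
    """Noise-free three-shape suite with ground truth, generated once."""
    from terma.synthetic import generate, standard_suite

    return [(spec, *generate(spec)) for spec in standard_suite(seed=0)]
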