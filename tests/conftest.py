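import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pulsemotif import make_pulse_train


@pytest.fixture
def ref_train():
    """The study's reference signal: A0 = 1, d0 = 10, f0 = 0.01."""
    return make_pulse_train(1.0, 10.0, 100.0)
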