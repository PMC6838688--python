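import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from opdt.protocol import IntensityScale, make_pulse_protocol
from opdt.synth import GroundTruthModel, simulate_pulse_session


@pytest.fixture(scope="session")
def default_scale():
    return IntensityScale.default()


@pytest.fixture(scope="session")
def small_session(default_scale):
    """A compact simulated session (20 levels x 6 blocks, 0.5-s ISI) with a
    mid-scale I50 so both PD and non-PD trials are plentiful."""
    protocol = make_pulse_protocol(default_scale, 6, 0.5, 10.0, seed=7)
    model = GroundTruthModel(a_true=10.0)
    session = simulate_pulse_session(protocol, model, seed=7)
    return session, protocol, model
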