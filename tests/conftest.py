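import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seqwta.builder import SerialOrderConfig, build_serial_order
from seqwta.protocols import TeachingProtocol, run_teaching

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def taught_k3():
    """A K=3 network taught A-B-C once with the default protocol.

    Session-scoped for speed; tests must not re-enable plasticity or
    overwrite the plastic weights (replay/probing are safe).
    """
    net = build_serial_order(SerialOrderConfig())
    protocol = TeachingProtocol(items=("A", "B", "C"))
    result = run_teaching(net, protocol, seed=11)
    assert not result.failures, result.failures
    net.set_plasticity(False)
    return net, protocol, result


@pytest.fixture()
def k3_network():
    return build_serial_order(SerialOrderConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
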