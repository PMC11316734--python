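import numpy as np
import pytest

import retvasc as rv

# stages used when a test needs a closed (capillarised) network but not the
# cosmetic stages (tortuosity, out-of-plane lifting)
CONNECTED_STAGES = ("seed", "leaves", "growth", "optimize", "trim",
                    "topology", "intersections", "macula", "capillaries")
GROWN_STAGES = ("seed", "leaves", "growth", "optimize", "trim",
                "topology", "intersections", "macula")


@pytest.fixture(scope="session")
def params():
    return rv.sample_parameters(0)


@pytest.fixture(scope="session")
def micro_net():
    """Small grown network (trees only, no capillaries), shared read-only."""
    net, domain, params, _ = rv.generate_retina(1, preset="micro",
                                                stages=GROWN_STAGES)
    return net, domain, params


@pytest.fixture(scope="session")
def mini_connected():
    """Mini retina with capillary bed and solved flow, shared read-only."""
    net, domain, params, _ = rv.generate_retina(2, preset="mini",
                                                stages=CONNECTED_STAGES)
    bc, sol = rv.solve_flow(net, params)
    return net, domain, params, bc, sol


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
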