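import numpy as np
import pytest

from slesim.network import build_small_world


@pytest.fixture(scope="session")
def topology():
    """Default 200+40 small-world topology, fixed seed."""
    return build_small_world(rng=np.random.default_rng(42))


@pytest.fixture(scope="session")
def small_topology():
    """A reduced network for fast engine tests."""
    return build_small_world(n_exc=60, n_inh=12, rng=np.random.default_rng(7),
                             n_groups=4)
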