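import numpy as np
import pytest

from pathmux.simulate import random_multiplex_network as random_multiplex  # noqa: F401


@pytest.fixture
def rng():
    return np.random.default_rng(0)
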