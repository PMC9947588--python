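import numpy as np
import pytest

from ctcdet.detector import NetworkConfig, build_detector, generate_anchors


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


#: a very small network profile used by unit tests (full six-scale structure,
#: sixteenth-width backbone on 150-px inputs)
TINY = NetworkConfig(input_size=150, width=0.0625)


@pytest.fixture(scope="session")
def tiny_config():
    return TINY


@pytest.fixture(scope="session")
def tiny_model():
    return build_detector(TINY, seed=7)


@pytest.fixture(scope="session")
def tiny_anchors():
    return generate_anchors(TINY)
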