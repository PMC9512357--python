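import numpy as np
import pytest

from phspdose.beam_model import load_beam_model


@pytest.fixture(scope="session")
def flattened_model():
    return load_beam_model(quality="flattened")


@pytest.fixture(scope="session")
def fff_model():
    return load_beam_model(quality="FFF")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220614)
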