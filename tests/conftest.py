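import numpy as np
import pytest

from fuselet import make_multifocus, make_multimodal, make_texture, make_pair


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def texture64():
    return make_texture((64, 64), seed=11)


@pytest.fixture(scope="session")
def multifocus_fixture():
    return make_multifocus(shape=(128, 128), sigma=3.0, split="left_right", seed=5)


@pytest.fixture(scope="session")
def multimodal_fixture():
    return make_multimodal(shape=(128, 128), noise_sigma=0.01, seed=5)


@pytest.fixture(scope="session")
def multimodal_pair(multimodal_fixture):
    return make_pair(multimodal_fixture.ct_like, multimodal_fixture.mr_like)
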