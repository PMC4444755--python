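import numpy as np
import pytest

from bubblestm import generate_base_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def base_image():
    return generate_base_image(128, 1.0, np.random.default_rng(42), image_id="img0")


@pytest.fixture(scope="session")
def small_image():
    return generate_base_image(64, 1.0, np.random.default_rng(43), image_id="small0")
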