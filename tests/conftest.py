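import numpy as np
import pytest

from isosynth.config import GeneratorConfig
from isosynth.phantom import LesionBank, generate_phantom_labels, synthetic_lesion_mask


@pytest.fixture(scope="session")
def phantom64():
    return generate_phantom_labels((64, 64, 64), 6, 3, seed=1)


@pytest.fixture(scope="session")
def phantom32():
    return generate_phantom_labels((32, 32, 32), 6, 3, seed=1)


@pytest.fixture(scope="session")
def lesion_bank():
    masks = [synthetic_lesion_mask((12, 12, 12), 2, (2.0, 4.0), seed=s) for s in range(3)]
    return LesionBank(masks)


@pytest.fixture()
def default_config():
    return GeneratorConfig()


@pytest.fixture()
def identity_config():
    return GeneratorConfig.identity_limit()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
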