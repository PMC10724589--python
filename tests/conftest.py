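import numpy as np
import pytest

from nutriadequacy import synthetic_data as sd


@pytest.fixture(scope="session")
def default_cfg():
    return sd.GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def crop_samples(default_cfg):
    return sd.generate_crop_samples(default_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
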