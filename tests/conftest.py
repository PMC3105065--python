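import numpy as np
import pytest

from crustgas.synthetic import GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def config():
    return GeneratorConfig(seed=42)


@pytest.fixture
def noiseless_config():
    return GeneratorConfig(
        seed=42,
        gas_noise_sd=0.0,
        delta_noise_sd=0.0,
        profile_noise_sd_fraction=0.0,
        ct_noise_sd=0.0,
    )
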