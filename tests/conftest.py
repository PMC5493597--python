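import numpy as np
import pytest

from micasa import AnalysisConfig, GeneratorSpec, make_condition


@pytest.fixture
def rng():
    return np.random.default_rng(20170530)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def noise_spec():
    return GeneratorSpec(
        pattern="white_noise",
        shape=(64, 64),
        pixel_size_um=2.0,
        pattern_params={"sigma": 1.0},
    )


@pytest.fixture
def noise_dataset(noise_spec):
    """Three white-noise image pairs, 64x64 at 2 um/px."""
    return make_condition(3, noise_spec, base_seed=11)
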