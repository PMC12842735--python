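import numpy as np
import pytest

from radimplant import RunConfig
from radimplant.synthetic import GeneratorParams, generate_dataset


@pytest.fixture(scope="session")
def easy_dataset():
    """130 easy 64x64 scenes: one implant, one design class per level."""
    params = GeneratorParams.easy(image_size=64)
    index, images = generate_dataset(130, params, seed=3)
    return index, images


@pytest.fixture(scope="session")
def full_scale_dataset():
    """20 full-scale 416x416 scenes with 1-3 implants and the full taxonomy."""
    params = GeneratorParams(image_size=416, n_implants_range=(1, 3))
    index, images = generate_dataset(20, params, seed=11)
    return index, images


@pytest.fixture()
def tiny_cfg():
    return RunConfig.tiny(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
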