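import datetime as dt

import numpy as np
import pytest

import canopyfeat as cf


@pytest.fixture(scope="session")
def easy_scene():
    return cf.generate_scene(seed=0)


@pytest.fixture(scope="session")
def small_scene():
    """A compact scene that keeps full-pipeline tests fast."""
    params = cf.CanopyParams(height=96, width=128, n_clusters=5)
    return cf.generate_scene(params, seed=7)


@pytest.fixture(scope="session")
def small_record(small_scene):
    meta = cf.ImageMetadata("small", 1, dt.date(2016, 5, 20), dt.date(2016, 6, 21))
    return cf.extract_features(small_scene.image, meta)


@pytest.fixture(scope="session")
def bank_and_mask(small_scene):
    stretched = cf.stretch_contrast(small_scene.image)
    mask = cf.segment(stretched)
    return cf.transform_bank(stretched, mask), mask


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
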