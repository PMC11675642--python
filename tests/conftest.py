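import numpy as np
import pytest

from hsiquant import PreprocessConfig, SyntheticConfig, apply_pipeline, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic dataset shared by read-only tests."""
    return generate_dataset(SyntheticConfig(n_samples=60, seed=11, image_size=24))


@pytest.fixture(scope="session")
def preprocessed_small(small_dataset):
    ss, state = apply_pipeline(small_dataset.spectra, PreprocessConfig())
    return ss, state


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
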