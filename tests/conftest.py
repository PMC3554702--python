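import numpy as np
import pytest

from gnosticfield import SynthConfig, generate_dataset
from gnosticfield.synthetic import split_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def unit_rows(X):
    return X / np.linalg.norm(X, axis=1, keepdims=True)


@pytest.fixture
def small_splits():
    """A small, easy 4-category, 1-channel train/test pair for pipeline tests."""
    cfg = SynthConfig(
        K=4, U=1, d=6, clusters_per_category=2, kappa=80.0,
        locations_per_stimulus=9, background_fraction=0.2,
        n_train=6, n_test=4, seed=7,
    )
    return split_dataset(generate_dataset(cfg))
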