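import warnings

import numpy as np
import pytest

import genesift as gs


@pytest.fixture(autouse=True)
def _quiet_model_warnings():
    # tree/boosting libraries emit benign convergence and feature-name
    # warnings on tiny fixtures
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def separable_fixture():
    """Two informative genes, class means +/-2, unit noise, n=60."""
    rng = np.random.default_rng(1)
    y = np.r_[np.zeros(30, int), np.ones(30, int)]
    shift = 2.0 * (2 * y - 1)
    X = np.column_stack([rng.normal(0, 1, 60) + shift, rng.normal(0, 1, 60) + shift])
    return X, y


@pytest.fixture
def small_planted():
    """A small planted dataset: 3 informative, 4 redundant, 60 noise genes."""
    ds, truth = gs.generate(
        gs.SyntheticSpec(
            n_pos=30, n_neg=30, n_informative=3, n_redundant=4, n_noise=60,
            effect_size=2.0, noise_sd=1.0, redundancy_noise_sd=0.1, seed=11,
        )
    )
    return ds, truth
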