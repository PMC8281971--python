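import logging

import numpy as np
import pytest

import pcper

logging.getLogger("pcper").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def blob_problem():
    """Compact, clearly separated 3-class problem where the method operates
    in its high-contrast membership regime (small data scale -> small C)."""
    spec = pcper.SyntheticSpec(
        M=3, n_per_class=20, d=2, separation=8.0, noise_sd=0.2,
        n_labeled_per_class=2, n_labeled_total=None, seed=7,
    )
    X, labels, truth, mask = pcper.make_problem(spec)
    return X, labels, truth, mask


@pytest.fixture(scope="session")
def blob_model(blob_problem):
    X, labels, truth, _ = blob_problem
    return pcper.fit(X, labels), X, labels, truth
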