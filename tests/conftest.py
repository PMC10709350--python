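import numpy as np
import pytest

from flairmatch.groups import build_group
from flairmatch.synthetic import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def table():
    return build_group()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny in-memory phantom cohort shared across tests."""
    cfg = PhantomConfig(shape=(32, 32, 16), n_labeled=24, n_unlabeled=8, seed=7)
    return generate_cohort(cfg)


def as_oriented(x, n_features):
    """(N, C*16, X, Y, Z) -> (N, C, 16, X, Y, Z) view helper."""
    return x.reshape(x.shape[0], n_features, 16, *x.shape[2:])
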