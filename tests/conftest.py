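import numpy as np
import pytest

from omrfdiff.model import GroupModel, OrdinalDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def binary_pair_model():
    """p=2 binary OMRF with unit interaction and zero thresholds."""
    return GroupModel(thresholds=[[0.0], [0.0]],
                      interactions=np.array([[0.0, 1.0], [1.0, 0.0]]))


def random_model(rng, p=3, ncat=None):
    """Small random OMRF for property tests."""
    if ncat is None:
        ncat = rng.integers(2, 4, size=p)
    thr = [rng.normal(0, 0.7, size=int(m) - 1) for m in ncat]
    sig = np.triu(rng.normal(0, 0.4, size=(p, p)), 1)
    return GroupModel(thresholds=thr, interactions=sig + sig.T)


def random_dataset(rng, model, n=20):
    ncat = model.n_categories
    X = np.stack([rng.integers(0, m, size=n) for m in ncat], axis=1)
    return OrdinalDataset(responses=X, n_categories=ncat)


@pytest.fixture
def small_model(rng):
    return random_model(rng)
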