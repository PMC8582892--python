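import numpy as np
import pytest

from somexposure.som import KohonenSOM, SupervisedKohonenSOM


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def blob_data():
    """Two well-separated Gaussian clusters with opposite labels."""
    rng = np.random.default_rng(77)
    n = 400
    X = np.vstack([
        rng.normal(0.0, 1.0, size=(n // 2, 4)),
        rng.normal(8.0, 1.0, size=(n // 2, 4)),
    ])
    y = np.repeat([0, 1], n // 2)
    perm = rng.permutation(n)
    return X[perm], y[perm]


@pytest.fixture(scope="session")
def trained_unsupervised(blob_data):
    X, _ = blob_data
    return KohonenSOM(X, grid=(5, 5)).fit(seed=1, n_epochs=20)


@pytest.fixture(scope="session")
def trained_supervised(blob_data):
    X, y = blob_data
    return SupervisedKohonenSOM(X, y, grid=(5, 5)).fit(seed=1, n_epochs=20)
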