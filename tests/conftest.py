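import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import winsorbnn as w

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

SMALL_ARCH = w.NetworkArchitecture((32, 32))
FAST_TRAIN = dict(epochs=300, patience=20)


@pytest.fixture(scope="session")
def smooth_dataset():
    """Noiseless smooth tabular regression, split 70/10/20."""
    ds = w.make_tabular_regression(500, 5, noise_sd=0.0, seed=4)
    return w.split_dataset(ds, (0.7, 0.1, 0.2), seed=0)


@pytest.fixture(scope="session")
def noisy_dataset():
    ds = w.make_tabular_regression(400, 4, noise_sd=0.5, seed=11)
    return w.split_dataset(ds, (0.7, 0.1, 0.2), seed=1)


@pytest.fixture(scope="session")
def bimodal_dataset():
    ds = w.make_multimodal_regression(1500, 2, seed=0)
    return w.split_dataset(ds, (0.7, 0.1, 0.2), seed=0)


@pytest.fixture(scope="session")
def gp_draw():
    """A single draw from a known GP (amplitude 1.5, lengthscale 2.0)."""
    rng = np.random.default_rng(1)
    X = np.sort(rng.uniform(-25, 25, size=(200, 1)), axis=0)
    K = w.rbf_kernel(X, X, 1.5, 2.0) + 1e-2 * np.eye(200)
    y = np.linalg.cholesky(K) @ rng.normal(size=200)
    return X, y
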