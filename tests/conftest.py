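import numpy as np
import pytest

from pardti import build_default_scheme
from pardti.phantom import assign_tissue_truth, make_phantom_labels


@pytest.fixture(scope="session")
def scheme():
    """Default 10 x b0 / 10 x b300 / 60 x b1100 acquisition."""
    return build_default_scheme(seed=0)


@pytest.fixture(scope="session")
def labels24():
    """Small phantom label map for fast per-module tests."""
    return make_phantom_labels((24, 24, 24), seed=0)


@pytest.fixture(scope="session")
def truth24(labels24):
    return assign_tissue_truth(labels24, jitter=0.05, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_symmetric(rng, scale=1.0):
    a = rng.standard_normal((3, 3)) * scale
    return (a + a.T) / 2.0


def random_spd_tensor(rng, lam_range=(0.1e-3, 2.5e-3)):
    """Random symmetric positive-definite tensor with eigenvalues in range."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    lam = rng.uniform(*lam_range, size=3)
    return q @ np.diag(lam) @ q.T
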