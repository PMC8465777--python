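import numpy as np
import pytest

from survforest.simgen import GeneratorSpec, make_replicate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def model_c_data():
    """One small model-C replicate shared by forest-level tests."""
    spec = GeneratorSpec("C", n_train=120, target_censoring=0.25, rho=0.0)
    return make_replicate(spec, np.random.default_rng(7))


def random_censored_sample(rng, n, censor_prob=0.3, tie_prob=0.3):
    """Right-censored sample with deliberate ties for property tests."""
    t = rng.exponential(1.0, n)
    if tie_prob and n > 2:
        k = rng.integers(0, n, size=int(n * tie_prob))
        t[k] = t[rng.integers(0, n, size=k.size)]
    t = np.maximum(t, 1e-6)
    e = (rng.random(n) > censor_prob).astype(int)
    return t, e
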