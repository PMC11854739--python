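import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("default", deadline=None)
_hyp_settings.load_profile("default")

from drfs.core_io import DataMatrix, remap_labels, standardize
from drfs.solver import SolverConfig, fit
from drfs.synthetic import reference_instance


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_data_matrix(rng, n=12, d=8, r=3):
    """Random labeled matrix with every class represented; labels canonical
    (first-appearance order, as the loader would produce)."""
    labels = np.concatenate([np.arange(1, r + 1), rng.integers(1, r + 1, size=n - r)])
    rng.shuffle(labels)
    return DataMatrix(values=rng.standard_normal((n, d)), labels=remap_labels(labels))


@pytest.fixture
def small_data(rng):
    return random_data_matrix(rng)


@pytest.fixture(scope="session")
def reference():
    X, gt = reference_instance()
    return X, gt


@pytest.fixture(scope="session")
def reference_std(reference):
    X, gt = reference
    return standardize(X), gt


@pytest.fixture(scope="session")
def reference_fit(reference_std):
    """One converged solve on the standardized reference fixture, shared."""
    Xs, gt = reference_std
    config = SolverConfig(alpha=1.0, beta=1.0, seed=0)
    return fit(Xs, config), config, Xs, gt
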