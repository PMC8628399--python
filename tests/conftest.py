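import numpy as np
import pytest

from clinaug.data_model import LabeledTable
from clinaug.synthetic_data import SyntheticSpec, generate, preset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(n_controls=10, n_cases=4, n_features=3, seed=0, shift=1.0, name="toy"):
    """Small imbalanced Gaussian table for unit tests."""
    r = np.random.default_rng(seed)
    x = r.normal(size=(n_controls + n_cases, n_features))
    y = np.zeros(n_controls + n_cases, dtype=int)
    y[n_controls:] = 1
    x[n_controls:] += shift
    return LabeledTable(x, y, name=name)


@pytest.fixture
def small_table():
    return make_table()


@pytest.fixture
def ccbr_table():
    """The 72-sample / 21-case benchmark preset (synthetic emulation)."""
    return generate(preset("ccbr", seed=7))


@pytest.fixture
def moderate_spec():
    return SyntheticSpec(n_samples=200, n_features=5, case_fraction=0.15,
                         effect_size=1.0, correlation=0.3, seed=11)
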