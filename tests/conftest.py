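import numpy as np
import pytest

from mpdetect import default_grid, gen_spectra_set, train_and_select
from mpdetect.synthetic import default_templates


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def labeled_spectra():
    """Default-generator training set: 600 spectra per class, seed 42."""
    return gen_spectra_set(600, 600, 0.5, seed=42)


@pytest.fixture(scope="session")
def trained_report(labeled_spectra):
    """Full development run (split, full model, selection, reduced model)."""
    return train_and_select(labeled_spectra, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
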