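import numpy as np
import pytest

from detrusorfit.synthetic import DEFAULT_GRID


@pytest.fixture
def grid() -> np.ndarray:
    """Default EFS frequency grid (Hz)."""
    return np.asarray(DEFAULT_GRID)


@pytest.fixture
def rng() -> np.random.Generator:
    """Seeded generator for reproducible randomized tests."""
    return np.random.default_rng(20220901)
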