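import numpy as np
import pytest

from wallspot import table1_preset


@pytest.fixture(scope="session")
def preset():
    """Baseline nondimensional parameter set used throughout the study."""
    return table1_preset()


@pytest.fixture(scope="session")
def y_grid():
    """Log-spaced positions spanning the wall thickness."""
    return np.geomspace(1e-4, 1.0, 200)
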