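import numpy as np
import pytest

from deepmarrow import phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A compact marrow phantom with full ground truth, shared across tests."""
    cells = phantom.CellPopulationSpec(n_b=12, n_plasma=30)
    stack, gt = phantom.generate_phantom(
        cells=cells, shape=(9, 160, 160), spacing=(3.0, 1.5, 1.5), seed=42)
    return stack, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
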