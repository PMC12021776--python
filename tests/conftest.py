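import numpy as np
import pytest

from habikit.preprocessing import DualPhaseCase, ImageGrid
from habikit.synthetic import default_phantom_spec, generate_phantom


@pytest.fixture(scope="session")
def phantom():
    """One default three-population phantom plus its ground truth."""
    return generate_phantom(default_phantom_spec(seed=7))


@pytest.fixture(scope="session")
def phantom_case(phantom):
    return phantom[0]


@pytest.fixture(scope="session")
def phantom_truth(phantom):
    return phantom[1]


@pytest.fixture()
def tiny_case():
    """A small hand-made aligned case (8 x 10 x 10, constant-ish)."""
    rng = np.random.default_rng(0)
    shape = (8, 10, 10)
    grid = ImageGrid(shape, (5.0, 1.0, 1.0))
    mask = np.zeros(shape, dtype=np.uint8)
    mask[2:6, 3:8, 3:8] = 1
    arterial = np.where(mask, rng.normal(100, 10, shape), -50.0)
    venous = np.where(mask, rng.normal(80, 10, shape), -50.0)
    return DualPhaseCase(arterial, venous, mask, grid, case_id="tiny")
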