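import numpy as np
import pytest

from strobetrack import CameraModel, CellGeometry, DiffusionModel
from strobetrack.simulate import rasterize_labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cell():
    """One spherocylinder in the middle of a 128 px field (um units)."""
    return CellGeometry(center=(4.2, 4.2), orientation=0.3, length=3.3, radius=0.5)


@pytest.fixture
def three_state_model():
    return DiffusionModel(D=[5.0, 0.5, 0.05], w=[0.80, 0.14, 0.06])


@pytest.fixture
def camera():
    return CameraModel(gain=2.0, offset=100.0, read_noise=1.5)


@pytest.fixture
def ideal_mask(cell):
    """Label mask of the single fixture cell at the default pixel size."""
    return rasterize_labels([cell], (128, 128))
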