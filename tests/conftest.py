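import numpy as np
import pytest

from synaptoquant import VoxelGeometry


@pytest.fixture
def geometry():
    """The confocal acquisition geometry: 0.21 µm pixels, 0.24 µm z-steps."""
    return VoxelGeometry(0.21, 0.24)


@pytest.fixture
def fine_geometry():
    """Finer, SIM-like sampling used for small receptor-field phantoms."""
    return VoxelGeometry(0.105, 0.12)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def bouton_center_px(truth, geometry):
    """ROI centre (y, x) in pixels for the first bouton of a phantom."""
    _, cy, cx = truth.bouton_centers[0]
    return (
        int(round(cy / geometry.pixel_size_xy - 0.5)),
        int(round(cx / geometry.pixel_size_xy - 0.5)),
    )
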