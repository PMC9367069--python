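import numpy as np
import pytest

from tissuegraph import LabeledImage, SyntheticTissueSpec, generate_voronoi_tissue


@pytest.fixture
def two_cell_image() -> LabeledImage:
    """Two rectangular cells abutting along 3 pixel faces, one channel."""
    labels = np.zeros((6, 8), dtype=np.int32)
    labels[1:4, 1:4] = 1  # 3x3 block
    labels[1:4, 4:7] = 2  # 3x3 block, touching along a 3-pixel column
    channel = np.where(labels == 1, 10.0, 0.0) + np.where(labels == 2, 20.0, 0.0)
    return LabeledImage(labels=labels, spacing=(1.0, 1.0), channels={"marker": channel})


@pytest.fixture
def gap_image() -> LabeledImage:
    """Two cells separated everywhere by a 1-pixel background ridge."""
    labels = np.zeros((6, 9), dtype=np.int32)
    labels[1:4, 1:4] = 1
    labels[1:4, 5:8] = 2
    return LabeledImage(labels=labels, spacing=(1.0, 1.0))


@pytest.fixture(scope="session")
def voronoi_tissue():
    """One small deterministic Voronoi tissue shared across tests."""
    spec = SyntheticTissueSpec(n_cells=25, shape=(256, 256), seed=11, min_separation=15.0)
    return generate_voronoi_tissue(spec)
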