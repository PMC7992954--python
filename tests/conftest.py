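import numpy as np
import pytest

from fructolyze.imaging import ImageFrame, SegmentationConfig
from fructolyze.synthetic import CellFieldSpec, generate_cell_images


@pytest.fixture(scope="session")
def clean_field():
    """One noise-free 100-cell field with 50 labeled cells."""
    spec = CellFieldSpec(n_cells=100, labeled_fraction=0.5, noise_sd=0.0, seed=7)
    return generate_cell_images(spec)[0]


@pytest.fixture(scope="session")
def noisy_field():
    """A realistic noisy field with 10% touching pairs."""
    spec = CellFieldSpec(n_cells=150, touching_fraction=0.1, seed=7)
    return generate_cell_images(spec)[0]


@pytest.fixture
def seg_config():
    return SegmentationConfig()


@pytest.fixture
def flat_frame():
    return ImageFrame(np.full((64, 64), 40.0))
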