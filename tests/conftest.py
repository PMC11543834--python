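import numpy as np
import pytest

from stromapipe.config import PipelineConfig
from stromapipe.io import MaskRaster, SpotGeometry


@pytest.fixture
def cfg():
    return PipelineConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_masks(rng, classes, shape=(40, 40), pixel_size=2.0):
    """Random partition rasters over the given classes (helper, not fixture)."""
    labels = rng.integers(0, len(classes), size=shape)
    return {
        cls: MaskRaster(mask=labels == i, pixel_size=pixel_size)
        for i, cls in enumerate(classes)
    }


@pytest.fixture(scope="session")
def small_study():
    """One shared desk-scale synthetic study for integration-style tests."""
    from stromapipe.simulate import simulate_study

    return simulate_study(
        PipelineConfig(seed=7), n_samples=4, n_genes=80, tissue_um=1600.0
    )
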