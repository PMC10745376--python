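import numpy as np
import pytest

from angiosprout import SyntheticChipSpec, generate_chip
from angiosprout.chip_geometry import build_chip_masks
from angiosprout.config import AnalysisConfig


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def default_chip():
    """One standard-density synthetic chip plus its ground truth."""
    return generate_chip(SyntheticChipSpec(seed=0))


@pytest.fixture(scope="session")
def default_masks(default_chip, config):
    channels, _ = default_chip
    return build_chip_masks(channels["nuclear"].image, config.geometry)


@pytest.fixture(scope="session")
def two_bar_image():
    """Hand-built nuclear projection: two bright horizontal bars on black.

    Bars are 400 x 20 px at rows 100-119 and 300-319 (centroid rows 109.5
    and 309.5), intensity 1000 over a zero background.
    """
    img = np.zeros((400, 400), dtype=np.uint16)
    img[100:120, :] = 1000
    img[300:320, :] = 1000
    return img
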