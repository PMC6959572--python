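import numpy as np
import pytest

from neuroquant.imaging import PixelGeometry
from neuroquant.synth import EngulfmentSceneParams, generate_engulfment_stack


@pytest.fixture(scope="session")
def small_scene():
    """A small noiseless engulfment scene shared by mask-level tests."""
    params = EngulfmentSceneParams(
        roi_size_um=(120.0, 140.0), n_microglia=6, noise_sd=0.0, seed=7
    )
    stack, truth = generate_engulfment_stack(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def default_scene():
    """One scene at the default study conditions (full ROI size)."""
    params = EngulfmentSceneParams(seed=3)
    stack, truth = generate_engulfment_stack(params)
    return params, stack, truth


@pytest.fixture
def geom_confocal():
    return PixelGeometry(0.27, 0.3)


@pytest.fixture
def geom_spine():
    return PixelGeometry(0.12, 0.3)


@pytest.fixture
def geom_exm():
    return PixelGeometry(0.155, 0.3)
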