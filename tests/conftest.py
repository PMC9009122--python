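import numpy as np
import pytest

from lysoquant import ImageSimParams, simulate_cell_image

# roomy geometry used where tests need many well-separated puncta
BIG_CELL = dict(
    image_size_px=(320, 320),
    nucleus_axes_px=((20.0, 28.0), (14.0, 20.0)),
    cytoplasm_to_nucleus_area_ratio=5.0,
)


@pytest.fixture(scope="session")
def default_field():
    """One simulated field with the default study-condition parameters."""
    params = ImageSimParams(seed=11)
    image, rois, truth = simulate_cell_image(params)
    return params, image, rois, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
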