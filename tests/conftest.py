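import numpy as np
import pytest

from morpholink import morphometry
from morpholink.synthetic import ShapeSpec, generate_shape_image


@pytest.fixture(scope="session")
def disk_image():
    """Centered disk r=200 px on a 512x512 canvas, with its truth table."""
    spec = ShapeSpec("disk", center=(256, 256), size=200, nucleus_radius=20)
    return generate_shape_image([spec], (512, 512), pixel_size_um=1.0, seed=0)


@pytest.fixture(scope="session")
def disk_measurements(disk_image):
    image, _ = disk_image
    labeled = morphometry.segment_cells(image)
    return morphometry.measure_shapes(labeled, image.pixel_size_um).iloc[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
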