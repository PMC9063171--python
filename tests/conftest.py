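import numpy as np
import pytest

from grainmetry.raster_io import RasterImage
from grainmetry.segmentation import label_components
from grainmetry.synthetic import SceneSpec, generate_scene, _superellipse_footprint


def region_from_mask(mask):
    """First labelled region of a boolean mask."""
    return label_components(np.asarray(mask, dtype=bool))[0]


def make_ellipse_region(a, b, angle_deg, squareness=2.0, center=(0.0, 0.0)):
    """A GrainRegion for one rasterized (super)ellipse with semi-axes a, b."""
    pad = a + 3
    cover, _, _ = _superellipse_footprint(
        a, b, angle_deg, pad + center[0], pad + center[1], squareness
    )
    canvas = np.zeros((2 * int(np.ceil(pad)) + 5, 2 * int(np.ceil(pad)) + 5), bool)
    h, w = cover.shape
    canvas[:h, :w] = cover > 0
    return region_from_mask(canvas)


@pytest.fixture(scope="session")
def small_scene():
    """A small exact-ellipse scene with per-grain ground truth."""
    spec = SceneSpec(
        n_grains=12, image_height=300, image_width=360, squareness=2.0, rng_seed=5
    )
    image, truth = generate_scene(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def default_scene():
    """One scene at the full default study conditions (450 superellipses)."""
    spec = SceneSpec(rng_seed=11)
    image, truth = generate_scene(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def measured_small_scene(small_scene):
    """Per-grain measurement table of the small scene at enhancement 10."""
    from grainmetry.descriptors import measure_image

    spec, image, truth = small_scene
    return measure_image(image, enhance=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def checker_image():
    """A 20x20 two-level brightness image: 40% at 50, 60% at 200."""
    px = np.full((20, 20), 200, dtype=np.uint8)
    px.ravel()[:160] = 50
    return RasterImage(np.repeat(px[:, :, None], 3, axis=2))
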