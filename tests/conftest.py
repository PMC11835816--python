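import numpy as np
import pytest
from hypothesis import settings

from kiwiphen.segmentation import SegmentationParams, segment_views
from kiwiphen.synthetic import PlantSpec, generate_plant_images

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def half_chlorotic():
    """A rendered plant-day with chlorosis_fraction = 0.5 (>10k side-view
    pixels), its ground truth, and cleanup-free masks."""
    spec = PlantSpec(
        plant_id="D-WL-01", cultivar="D", treatment="WL", daw=4,
        leaf_count=6, leaf_radius_px=30, chlorosis_fraction=0.5,
        water_content=0.6, seed=7, image_shape=(200, 260),
    )
    images, truth = generate_plant_images(spec)
    masks = segment_views(images.rgb, SegmentationParams().without_cleanup())
    return spec, images, truth, masks


@pytest.fixture(scope="session")
def chlorosis_ladder():
    """Fixtures spanning chlorosis_fraction 0 -> 1 at fixed geometry/seed."""
    out = []
    for frac in np.linspace(0.0, 1.0, 6):
        spec = PlantSpec(
            plant_id="H-WL-01", cultivar="H", treatment="WL", daw=2,
            leaf_count=5, leaf_radius_px=24, chlorosis_fraction=float(frac),
            seed=11, image_shape=(160, 200),
        )
        out.append((spec, *generate_plant_images(spec)))
    return out
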