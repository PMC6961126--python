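import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mixed_scene():
    """A 100-cell field with known multinucleation mix (session-cached)."""
    from cardiopheno.synthetic import simulate_image_scene

    scene, truth = simulate_image_scene(
        n_cells=100, nuclei_count_probs=(0.6, 0.3, 0.1), seed=1)
    return scene, truth


@pytest.fixture(scope="session")
def mixed_segmentation(mixed_scene):
    from cardiopheno.segmentation import segment_scene

    scene, _ = mixed_scene
    return segment_scene(scene)


def disk_image(shape, centers_px, radius_px, level=1000.0):
    """Rasterize bright disks on a zero background."""
    img = np.zeros(shape)
    yy, xx = np.indices(shape, dtype=float)
    for cy, cx in centers_px:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px ** 2] = level
    return img
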