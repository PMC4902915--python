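import numpy as np
import pytest

from ryeview import (
    RasterImage,
    SceneParams,
    SegmentationConfig,
    generate_scene,
    segment_all,
)


@pytest.fixture(scope="session")
def default_cfg() -> SegmentationConfig:
    return SegmentationConfig.for_scale(SceneParams().pixels_per_cm)


@pytest.fixture(scope="session")
def default_scene():
    return generate_scene(SceneParams(seed=1))


@pytest.fixture(scope="session")
def default_scene_masks(default_scene, default_cfg):
    return segment_all(default_scene.image, default_cfg, image_id="scene1")


@pytest.fixture(scope="session")
def disk_image():
    """128x128 large bright disk (200) on a dark field (40), GRAY8.

    The disk is large relative to the edge operators' ~2 px support, so a
    correctly filled edge ring reproduces it with high overlap.
    """
    yy, xx = np.ogrid[:128, :128]
    disk = (yy - 64) ** 2 + (xx - 64) ** 2 <= 55**2
    img = np.where(disk, 200, 40).astype(np.uint8)
    return RasterImage(img, "GRAY8"), disk
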