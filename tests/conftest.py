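import numpy as np
import pytest

from goatpheno.config import synthetic_cohort_config
from goatpheno.segmentation import segment
from goatpheno.synth import BACKDROP_BLUE, generate_scene
from goatpheno.types import ImageRecord, SceneParams


@pytest.fixture(scope="session")
def cfg():
    return synthetic_cohort_config()


@pytest.fixture(scope="session")
def sign_scene(cfg):
    """One clean sign-pose scene shared across read-only tests."""
    return generate_scene(SceneParams(pose="sign", seed=1), cfg.sign)


@pytest.fixture(scope="session")
def sign_mask(cfg, sign_scene):
    rec, _ = sign_scene
    return segment(rec, cfg)


@pytest.fixture(scope="session")
def rear_scene(cfg):
    return generate_scene(SceneParams(pose="rear", seed=1), cfg.sign)


def rect_scene(shape=(200, 300), box=(50, 150, 80, 220), color=(196, 154, 96)):
    """A rectangular subject on protocol blue: every boundary is an ideal
    colour step, the simplest ground-truthed step-edge scene."""
    img = np.zeros((*shape, 3), np.uint8)
    img[:] = BACKDROP_BLUE
    truth = np.zeros(shape, bool)
    truth[box[0] : box[1], box[2] : box[3]] = True
    img[truth] = color
    return ImageRecord(img, "side", "rect"), truth


@pytest.fixture()
def rect():
    return rect_scene()
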