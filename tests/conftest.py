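import warnings

import numpy as np
import pytest

from lasertrace import SimConfig, build_default_pattern

# skimage deprecation chatter from ProjectiveTransform.estimate
warnings.filterwarnings("ignore", category=FutureWarning)

# Reduced-scale scene for unit tests: same geometry and camera model as the
# full 1280x720 default, but ~1.1 px/mm and a brisk trace so a full trial is
# a few hundred frames.
QUICK_SCENE = dict(image_dims=(640, 360), speed_mean_mm_s=120.0)


@pytest.fixture
def pattern():
    return build_default_pattern()


@pytest.fixture
def quick_sim():
    return SimConfig(**QUICK_SCENE, seed=7)


def make_quick_sim(**overrides) -> SimConfig:
    kw = dict(QUICK_SCENE)
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
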