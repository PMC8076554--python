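import math

import numpy as np
import pytest

from gazesim.planner import RenderContext, demo_policy
from gazesim.render import LightSource
from gazesim.scene import build_demo_library
from gazesim.viewpoint import build_retinal_array


@pytest.fixture(scope="session")
def demo_library():
    return build_demo_library()


@pytest.fixture(scope="session")
def small_ctx():
    """Low-resolution render context: fast, but still resolves the demo objects."""
    return RenderContext(
        array=build_retinal_array(16, 16, math.radians(40.0)),
        light=LightSource(),
        resolution=6,
    )


@pytest.fixture(scope="session")
def corner_policies():
    return {c: demo_policy(c) for c in ("southeast", "northeast", "southwest", "northwest")}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
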