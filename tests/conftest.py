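import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from aecvision.environment import EyePose, WorldState, make_texture


@pytest.fixture(scope="session")
def pink_texture():
    return make_texture(seed=11, kind="pink_noise", side=512)


@pytest.fixture(scope="session")
def blocks_texture():
    return make_texture(seed=12, kind="blocks", side=512)


@pytest.fixture()
def world(pink_texture):
    return WorldState(stimulus_texture=pink_texture,
                      stimulus_center=np.array([0.0, 0.0, 1.5]))


@pytest.fixture()
def eyes():
    return EyePose()
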