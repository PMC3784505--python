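import numpy as np
import pytest

from vibrisim import Params
from vibrisim.attention import GridSpec
from vibrisim.plane import HeadPose, build_morphology


@pytest.fixture(scope="session")
def params():
    return Params()


@pytest.fixture(scope="session")
def grid(params):
    return GridSpec(params)


@pytest.fixture(scope="session")
def morphs(params):
    return build_morphology(params)


@pytest.fixture()
def pose0(params):
    return HeadPose(fovea=np.zeros(2),
                    neck=np.array([-params.fovea_neck_sep, 0.0]))


@pytest.fixture(scope="session")
def free_log():
    """One 30 s obstacle-free run, shared by the analyses that need it."""
    from vibrisim import engine
    return engine.run(Params(), duration=30.0, seed=1)
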