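import numpy as np
import pytest

import coilswim as cs


@pytest.fixture(scope="session")
def single_model():
    return cs.build_single_coiling()


@pytest.fixture(scope="session")
def double_model():
    return cs.build_double_coiling(rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def beat_glide_model():
    return cs.build_beat_and_glide("base", rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def single_run(single_model):
    """The base 10 s single-coiling simulation, shared across tests."""
    return cs.run(single_model, 10000.0, seed=1)


@pytest.fixture(scope="session")
def single_kinematics(single_run):
    from coilswim.musculoskeletal import body_kinematics

    return body_kinematics(single_run)
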