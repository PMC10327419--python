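import numpy as np
import pytest

from reachreflex.kinematics import ArmModel
from reachreflex.reflex import quantify_session
from reachreflex.simulator import control_preset, generate_session, stroke_preset


@pytest.fixture(scope="session")
def arm():
    return ArmModel(upper_arm_length=0.30, forearm_length=0.35)


@pytest.fixture(scope="session")
def stroke_session():
    """One quantified stroke-preset session, shared across tests."""
    sess = generate_session(stroke_preset(), seed=7)
    result, mvc, mvv = quantify_session(sess)
    return sess, result, mvc, mvv


@pytest.fixture(scope="session")
def control_session():
    sess = generate_session(control_preset(), seed=7)
    result, mvc, mvv = quantify_session(sess)
    return sess, result, mvc, mvv


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
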