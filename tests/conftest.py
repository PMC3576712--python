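import numpy as np
import pytest

from dqkin.rigid import RotationSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_axis(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def random_rotation_spec(rng, max_angle=np.pi):
    return RotationSpec(random_axis(rng), rng.uniform(-max_angle, max_angle))


@pytest.fixture
def random_axis_fn():
    return random_axis


@pytest.fixture
def random_rotation_spec_fn():
    return random_rotation_spec
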