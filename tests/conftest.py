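import numpy as np
import pytest

from mpcasl import bloch, phantom


@pytest.fixture(scope="session")
def operating_geom():
    """Paper operating point: 2 mm labelling plane."""
    return bloch.LabelGeometry(label_thickness=2.0)


@pytest.fixture(scope="session")
def operating_spin():
    return bloch.FlowingSpin(velocity=124.0, t1_blood=2.1, t2_blood=0.033)


@pytest.fixture(scope="session")
def fast_geom():
    """Thin plane + fast spin: short transit, quick simulations."""
    return bloch.LabelGeometry(label_thickness=1.0)


@pytest.fixture(scope="session")
def fast_spin():
    return bloch.FlowingSpin(velocity=200.0, t1_blood=2.1, t2_blood=0.033)


@pytest.fixture(scope="session")
def small_phantom():
    """Small deterministic phantom shared by read-only tests."""
    return phantom.make_mouse_phantom(seed=11, shape=(32, 32, 4))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
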