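import warnings

import numpy as np
import pytest

from trackrel.config import AcquisitionSpec, MotionSpec, PhantomSpec
from trackrel.pipeline import make_fixtures


@pytest.fixture(scope="session")
def study_bundle():
    """Miniature end-to-end paired study (deterministic, ~20 s once)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_fixtures(seed=1)


@pytest.fixture()
def phantom():
    return PhantomSpec()


@pytest.fixture()
def quiet_acq():
    return AcquisitionSpec(noise_model="none", n_frames=40)


@pytest.fixture()
def slow_motion():
    return MotionSpec()  # cos4, 7.5 mm, 5 s


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
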