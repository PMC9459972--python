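import numpy as np
import pytest

from facesym import generate_template
from facesym.registration import RegistrationConfig


@pytest.fixture(scope="session")
def template_478():
    """Neutral mirror-symmetric template + topology, full face-mesh mode."""
    return generate_template("full_478")


@pytest.fixture(scope="session")
def template_68():
    return generate_template("compact_68")


@pytest.fixture(scope="session")
def fast_cfg():
    """Registration config with a coarse sweep, for unit-test speed."""
    return RegistrationConfig(sweep_stride=50)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
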