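import numpy as np
import pytest

from mitoclamp.thermo import ClampState, default_constants


@pytest.fixture
def constants():
    return default_constants()


@pytest.fixture
def resting_state():
    """The resting-demand clamp composition (30 mM PCr step)."""
    return ClampState(atp_mM=5.0, pcr_mM=30.0, cr_mM=5.0, pi_mM=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
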