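import numpy as np
import pytest

from flapsm.simulate import PhotophysicsModel, TwoStateKinetics


@pytest.fixture
def quiet_phys():
    """Noise-free detection model for exact-value tests."""
    return PhotophysicsModel(total_brightness=1000.0, noise_model="none")


@pytest.fixture
def tirf_phys():
    """Poisson-noise detection model at realistic TIRF count levels."""
    return PhotophysicsModel(
        total_brightness=500.0, background_donor=20.0, background_acceptor=20.0
    )


@pytest.fixture
def flap_kinetics():
    """Two-state conformational exchange with the flap-substrate E levels."""
    return TwoStateKinetics(k_forward=8.0, k_backward=2.0, E_state1=0.37, E_state2=0.6)
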