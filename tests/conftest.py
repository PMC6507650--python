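import numpy as np
import pytest

from sacsize.growth import CycleTimeModel, GrowthParams


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def params():
    """Default growth parameters (A0=20, Amax=120, T=100, m=0.3)."""
    return GrowthParams()


@pytest.fixture
def params_m0():
    """Pure logistic curve (m=0): saturates at Amax."""
    return GrowthParams(m=0.0)


@pytest.fixture
def unperturbed():
    return CycleTimeModel.unperturbed()


@pytest.fixture
def sac():
    return CycleTimeModel.sac_active()
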