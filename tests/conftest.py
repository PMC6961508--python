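import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bioassay():
    from rbgof import load_fixture

    return load_fixture("bioassay").data


@pytest.fixture(scope="session")
def design_m5():
    """Intercept + x2 on the odd grid 1..9 (the m=5 simulation design)."""
    return np.column_stack([np.ones(5), [1.0, 3.0, 5.0, 7.0, 9.0]])


@pytest.fixture(scope="session")
def theta_m5_false():
    """Off-surface truth used in the misspecification simulations."""
    return np.array([0.875, 0.327, 0.107, 0.198, 0.908])
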