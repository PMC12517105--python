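import numpy as np
import pytest

from alidose.params import default_parameter_set


@pytest.fixture(scope="session")
def efflux_params():
    """With-induction parent + active-efflux metabolite presets."""
    return default_parameter_set("with_induction", "efflux")


@pytest.fixture(scope="session")
def passive_params():
    return default_parameter_set("no_induction", "passive")


@pytest.fixture(scope="session")
def coarse_grid():
    """The optimization experiment's sampling times."""
    return np.array([0.0, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0])


DOSE = 8.6  # nmol measured at 0 h in the optimization experiment


@pytest.fixture(scope="session")
def dose():
    return DOSE
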