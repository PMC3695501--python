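import numpy as np
import pytest

import mnmekin as mk


@pytest.fixture(scope="session")
def wt():
    return mk.wt_parameters()


@pytest.fixture(scope="session")
def wt_states(wt):
    """Noiseless wild-type single-turnover run at the standard 2.5 uM mix."""
    grid = np.arange(0.0, 17.0 + 1e-9, 0.01)
    return mk.simulate_cycle(wt, 2.5, 2.5, t_grid=grid)


@pytest.fixture(scope="session")
def wt_mant(wt_states):
    return mk.project_observable(wt_states, "mant")
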