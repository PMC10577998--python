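import warnings

import numpy as np
import pytest

from tmlecat.synthetic import SimConfig, generate_panel


@pytest.fixture(scope="session")
def baseline_panel():
    """Desk-scale baseline draw shared by read-only tests."""
    panel, truth = generate_panel(SimConfig.for_scenario("baseline", seed=0))
    return panel, truth


@pytest.fixture(scope="session")
def large_baseline_panel():
    panel, truth = generate_panel(
        SimConfig.for_scenario("baseline", n_countries=5000, seed=1))
    return panel, truth


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning)
        yield


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
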