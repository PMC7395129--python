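import numpy as np
import pytest

from cogload import simulate


@pytest.fixture(scope="session")
def short_layout():
    return simulate.default_layout(task_s=120.0, rest_s=60.0, baseline_s=60.0)


@pytest.fixture(scope="session")
def short_config(short_layout):
    return simulate.SimulationConfig(n_subjects=1, seed=7, layout=short_layout)


@pytest.fixture(scope="session")
def fnirs_session(short_config):
    """One simulated subject with fNIRS only (reused across tests)."""
    return simulate.simulate_subject(
        short_config, "S01", np.random.default_rng(7), signals=("fnirs",)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
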