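import numpy as np
import pytest

from connfp import SimulationConfig, make_toy_atlas, simulate_subject


@pytest.fixture(scope="session")
def toy_atlas():
    return make_toy_atlas((16, 16, 12))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def hub_subject(toy_atlas):
    """One synthetic subject with a left-mesial hub, plus its config."""
    cfg = SimulationConfig(
        grid_dims=(16, 16, 12), n_volumes=60, seed=7,
        n_controls=2, n_patients=2,
    )
    vol, conf = simulate_subject(
        cfg, toy_atlas, hub_spec=[("mesial", "left", 1.0)], seed=7
    )
    return cfg, vol, conf
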