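import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dl_fov():
    """One small simulated diffraction-limited FOV shared across tests."""
    from aggrekit.sim.diffraction import DLSimParams, simulate_dl

    params = DLSimParams(image_size=256, n_dots=20, seed=42)
    ideal, noisy, truth = simulate_dl(params)
    return params, ideal, noisy, truth
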