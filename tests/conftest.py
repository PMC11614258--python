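import numpy as np
import pytest

import hyperplume as hp


@pytest.fixture(scope="session")
def noiseless_scene():
    """Stock four-patch scene with no sensor noise and no gradient."""
    spec = hp.default_scene(noise_sd=0.0, gradient_amplitude=0.0, seed=11)
    return hp.simulate_cube(spec)


@pytest.fixture(scope="session")
def noisy_scene():
    """Stock scene at the default noise and gradient settings."""
    spec = hp.default_scene(seed=11)
    return hp.simulate_cube(spec)


@pytest.fixture(scope="session")
def receptors():
    return hp.vs_bird_receptors()


@pytest.fixture()
def small_cube():
    """Tiny deterministic cube for I/O tests."""
    rng = np.random.default_rng(5)
    data = rng.uniform(0, 1, size=(4, 5, 6)).astype(np.float32)
    wl = np.linspace(400, 650, 6)
    return hp.HyperCube(data, wl, interleave="bil")
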