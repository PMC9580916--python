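import numpy as np
import pytest

import smlmkit as sk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def static_bright_movie():
    """50-frame movie of 3 always-on bright emitters on flat background."""
    emitters = sk.EmitterModel(
        positions=[[10.3, 20.7], [25.2, 8.4], [8.6, 6.2]],
        k_on=1.0, k_off=0.0, photons_per_frame=5000, initial_on_fraction=1.0,
    )
    noise = sk.NoiseModel(background_offset=20, read_noise_sigma=1.0)
    movie, truth = sk.simulate_movie(emitters, noise, None, 50, (32, 32), seed=7)
    return movie, truth, emitters


@pytest.fixture
def blinking_movie():
    """200-frame movie of sparse blinking emitters with inhomogeneous background."""
    rg = np.random.default_rng(3)
    positions = rg.uniform(5, 43, size=(12, 2))
    emitters = sk.EmitterModel(
        positions, k_on=0.05, k_off=0.6, photons_per_frame=4000,
    )
    noise = sk.NoiseModel(
        background_offset=30, background_gradient=(0.3, -0.2), read_noise_sigma=1.5,
    )
    movie, truth = sk.simulate_movie(emitters, noise, None, 200, (48, 48), seed=11)
    return movie, truth
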