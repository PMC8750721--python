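import numpy as np
import pytest

from calyxscan import SceneConfig, generate_scene
from calyxscan.calibration import calibrate
from calyxscan.hypercube import Hypercube


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_cube(rng):
    """8×8×16 cube with a uniform 900–1700 nm wavelength grid."""
    data = rng.uniform(0.0, 1.0, size=(8, 8, 16))
    return Hypercube(data, np.linspace(900, 1700, 16), name="small")


@pytest.fixture(scope="session")
def noiseless_scene():
    """One noise-free infested apple scene (exactly invertible calibration)."""
    cfg = SceneConfig(seed=7, noise_additive_sd=0.0, noise_multiplicative_sd=0.0,
                      dark_noise_sd=0.0)
    return cfg, generate_scene(cfg)


@pytest.fixture(scope="session")
def calibrated_scene():
    """A realistic noisy infested scene, already calibrated, plus its truth."""
    cfg = SceneConfig(seed=11)
    raw, refs, truth = generate_scene(cfg)
    return cfg, calibrate(raw, refs), truth
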