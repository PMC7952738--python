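import numpy as np
import pytest

import octatlas as oa
from octatlas.synthetic import _default_enface_grid


@pytest.fixture(scope="session")
def small_config():
    return oa.CohortConfig(n_per_group={"MNV": 3, "MA": 3, "NONP": 3}, seed=42)


@pytest.fixture(scope="session")
def phantom(small_config):
    return oa.generate_eye_phantom(small_config, "MNV", seed=5)


@pytest.fixture(scope="session")
def clean_visit(phantom):
    """Noise-free rendering of visit 0 (identity misalignment)."""
    return oa.render_visit(phantom, 0, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def noisy_visit(phantom):
    return oa.render_visit(phantom, 0, noise_sd=4.0, seed=1)


@pytest.fixture(scope="session")
def enface_grid():
    return _default_enface_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(123)
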