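import numpy as np
import pytest

from denrefine import build_topology, make_bundle, make_helix, make_observations


@pytest.fixture(scope="session")
def helix5():
    return make_helix(5)


@pytest.fixture(scope="session")
def helix20():
    return make_helix(20)


@pytest.fixture(scope="session")
def bundle():
    return make_bundle(3, 8, spacing=10.0)


@pytest.fixture(scope="session")
def helix20_obs(helix20):
    """Noise-free self-consistent amplitudes for the 20-residue helix."""
    return make_observations(helix20, d_min=3.5, noise_frac=0.0, seed=42)


@pytest.fixture(scope="session")
def helix5_topology(helix5):
    return build_topology(helix5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
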