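import numpy as np
import pytest

from drum.fixtures import (
    build_tisochrysis_model,
    generate_synthetic_observations,
    simulate_tisochrysis,
)


@pytest.fixture(scope="session")
def tiso():
    return build_tisochrysis_model()


@pytest.fixture(scope="session")
def periodic_traj(tiso):
    """Fixture trajectory well inside the periodic regime (transient discarded)."""
    return simulate_tisochrysis(tiso, n_cycles=3, transient_cycles=20,
                                points_per_hour=8)


@pytest.fixture(scope="session")
def noiseless_ds(tiso):
    """Noise-free synthetic observations from the packaged parameter vector."""
    return generate_synthetic_observations(tiso, noise_sd=0.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
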