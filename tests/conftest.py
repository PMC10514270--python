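import numpy as np
import pytest

import lymphtile as lt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def poisson_net():
    return lt.generate_fixture(
        "poisson-segments",
        {"side": 2000.0, "intensity": 5e-5, "mean_seg_length": 60.0},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim():
    """One short scaled-down growth run shared by read-only tests."""
    params = lt.preset("wt", scale=0.25, duration=10.0)
    return lt.run_simulation(params, seed=11)


@pytest.fixture(scope="session")
def wt_sim():
    """One full-length scaled-down wild-type run shared by read-only tests."""
    params = lt.preset("wt", scale=0.3)
    return lt.run_simulation(params, seed=5)
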