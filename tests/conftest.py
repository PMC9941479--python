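import numpy as np
import pytest

from wbgtgrid import SyntheticConfig, generate_grid


@pytest.fixture(scope="session")
def small_grid():
    """Two synthetic days on a 3x4 warm-humid grid (hourly)."""
    return generate_grid(SyntheticConfig(seed=42, n_lat=3, n_lon=4, n_days=2))


@pytest.fixture(scope="session")
def random_states():
    """Seeded random point states spanning the method's working range."""
    rng = np.random.default_rng(2023)
    n = 2000
    ta = rng.uniform(240.0, 320.0, n)
    tmrt = ta + rng.uniform(-10.0, 40.0, n)
    va = rng.uniform(0.0, 20.0, n)
    td = ta - np.abs(rng.normal(5.0, 4.0, n))
    return ta, td, va, tmrt
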