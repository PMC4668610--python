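import numpy as np
import pytest

from emgshift import (
    build_grid,
    make_motion_model,
    simulate_session,
)


@pytest.fixture(scope="session")
def full_grid():
    """The 8x24, 10 mm montage used throughout the experimental design."""
    return build_grid(8, 24, 10.0)


@pytest.fixture(scope="session")
def small_grid():
    return build_grid(4, 6, 10.0)


@pytest.fixture(scope="session")
def small_session(small_grid):
    """Short 5-motion session on a small grid, cheap enough for unit tests."""
    model = make_motion_model(small_grid, n_motions=5, n_sources=4,
                              active_per_motion=2, seed=11)
    return simulate_session(model, n_trials=3, duration_s=1.0, fs=1024.0,
                            seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, dim, scale=1.0):
    a = rng.standard_normal((dim, dim))
    return scale * (a @ a.T + dim * 0.05 * np.eye(dim))
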