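import numpy as np
import pytest

from placenav import ArenaConfig, FieldParams, build_arena


@pytest.fixture(scope="session")
def ref_config() -> ArenaConfig:
    """Reference setup: 15x15 lattice, start (1,1), target (10,10)."""
    return ArenaConfig()


@pytest.fixture(scope="session")
def lattice15(ref_config):
    return build_arena(ref_config)


@pytest.fixture(scope="session")
def params4() -> FieldParams:
    return FieldParams(sigma1=4.0, sigma2=4.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config() -> ArenaConfig:
    """Compact arena for fast session-level tests."""
    return ArenaConfig(
        grid_rows=9,
        grid_cols=9,
        start=(2.0, 2.0),
        target=(7.0, 7.0),
        sigma1=3.0,
        sigma2=3.0,
        n_trials=4,
        max_steps_per_trial=4000,
        seed=7,
    )
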