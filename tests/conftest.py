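import numpy as np
import pytest

from glyswitch.catalog import build_config, table1_catalog


@pytest.fixture(scope="session")
def catalog():
    return table1_catalog()


@pytest.fixture(scope="session")
def cfg_no_loops():
    """PFKP + PKM1: neither regulatory loop active."""
    return build_config("PFKP", "PKM1", 10.0)


@pytest.fixture(scope="session")
def cfg_loop1():
    """PFKL + PKM1: only the F16BP->PFK feedback loop."""
    return build_config("PFKL", "PKM1", 10.0)


@pytest.fixture(scope="session")
def cfg_loop2():
    """PFKP + PKM2: only the PK/PFKFB/F26BP composite loop."""
    return build_config("PFKP", "PKM2", 10.0)


@pytest.fixture(scope="session")
def cfg_both():
    """PFKL + PKM2: both loops active."""
    return build_config("PFKL", "PKM2", 10.0)


@pytest.fixture(scope="session")
def hela_cfg():
    from glyswitch.experiments import hela_like_config
    return hela_like_config()


@pytest.fixture(scope="session")
def both_states_5mm(cfg_both):
    """Steady states of the both-loops model at 5 mM glucose (bistable)."""
    from glyswitch.steady_state import find_steady_states
    return find_steady_states(5.0, cfg_both, n_starts=40, seed=1,
                              method="reduction")


def rng(seed=0):
    return np.random.default_rng(seed)
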