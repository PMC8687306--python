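import warnings

import numpy as np
import pytest

from fluctid import TimeGrid, build_gene_expression, build_immigration_death

warnings.filterwarnings("ignore", message="non-integer initial copy numbers")


@pytest.fixture(scope="session")
def id_net():
    """Immigration-death network at the reference truth (θ1, θ2) = (1, 0.1)."""
    return build_immigration_death(1.0, 0.1, 10)


@pytest.fixture(scope="session")
def ge_net():
    return build_gene_expression()


@pytest.fixture(scope="session")
def grid100():
    """The standard stationary sampling design: 100 samples, Δt = 0.5."""
    return TimeGrid(0.0, 100, 0.5)


@pytest.fixture(scope="session")
def long_stationary_series(id_net):
    """One long stationary immigration-death trajectory for distributional checks."""
    from fluctid import simulate_ssa

    grid = TimeGrid(0.0, 200_000, 0.5)
    return simulate_ssa(id_net, grid, 20240901).values[:, 0]


def pytest_configure(config):
    np.seterr(all="warn")
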