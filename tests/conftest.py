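import pytest

from tolpal.frap import FrapProtocol, simulate_frap, synthetic_bleach_function
from tolpal.model import (
    SpeciesTotals,
    TolPalParams,
    make_grid,
    tolpal_steady_state,
)


@pytest.fixture(scope="session")
def table_params() -> TolPalParams:
    """The fitted/literature parameter set used throughout."""
    return TolPalParams()


@pytest.fixture(scope="session")
def totals() -> SpeciesTotals:
    return SpeciesTotals()


@pytest.fixture(scope="session")
def dividing_steady(table_params, totals):
    """Steady state of a dividing cell (L = 4 um, septal transport)."""
    grid = make_grid(4.0, 81)
    beta = table_params.transport_profile(grid, "truncated_normal")
    return beta, tolpal_steady_state(table_params, beta, totals)


@pytest.fixture(scope="session")
def nondividing_steady(table_params, totals):
    """Steady state of a non-dividing cell (L = 2.8 um, uniform transport)."""
    grid = make_grid(2.8, 81)
    beta = table_params.transport_profile(grid, "homogeneous")
    return beta, tolpal_steady_state(table_params, beta, totals)


@pytest.fixture(scope="session")
def pal_dividing_kymo(table_params, totals, dividing_steady):
    """A noiseless Pal FRAP kymograph of a dividing cell."""
    beta, steady = dividing_steady
    protocol = FrapProtocol.pal_default()
    bleach = synthetic_bleach_function(protocol, beta.grid, edge_sigma=0.05)
    return simulate_frap(table_params, beta, totals, protocol, bleach,
                         steady=steady)
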