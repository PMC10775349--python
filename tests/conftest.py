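import numpy as np
import pytest

from doserr.sim_core import (
    DoseGrid,
    ErrorSpec,
    RiskModel,
    default_grid,
    simulate_cases,
    simulate_dose_ensemble,
)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def small_grid():
    """Down-scaled grid (same dose structure, ~1% of the individuals)
    for fast simulation in unit tests."""
    return DoseGrid(
        group_edges=((0.0, 0.07), (0.08, 0.19), (0.20, 0.99), (1.00, 2.49), (2.50, None)),
        central_doses=np.array([0.02, 0.13, 0.45, 1.5, 2.0]),
        person_years=np.array([2.5e6, 3.6e5, 4.5e5, 1.6e5, 5.0e4]),
        n_individuals=np.array([500, 72, 90, 32, 10]),
    )


@pytest.fixture(scope="session")
def linear_truth():
    return RiskModel(alpha=3.0)


@pytest.fixture(scope="session")
def lq_truth():
    return RiskModel(alpha=0.25, beta=2.0)


@pytest.fixture(scope="session")
def zero_error_meta(small_grid, linear_truth):
    """A degenerate (zero dose error) meta-simulation: doses equal the
    central doses exactly in every sub-simulation."""
    ens = simulate_dose_ensemble(small_grid, ErrorSpec(), m=5, rng_seed=11)
    cases = simulate_cases(ens, linear_truth, n_cases=250, rng_seed=12)
    return ens, cases
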