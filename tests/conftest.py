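import numpy as np
import pytest

from cellsym import make_template, simulate_population
from cellsym.synthetic import PopulationParams


def zeroed_params(**overrides) -> PopulationParams:
    """Params with every variance component off; tests switch on what they need."""
    base = dict(
        n_cells=8,
        n_replicates=1,
        sd_symmetric=0.0,
        sd_asymmetric={"semicell": 0.0, "left-right": 0.0, "semicell*left-right": 0.0},
        lls_char_sd={},
        uls_char_sd={},
        lobule_char_sd_default=0.0,
        lobule_symmetric_sd_default=0.0,
        log_size_sd=0.0,
        allometry_slope=0.0,
        sd_measurement_error=0.0,
    )
    base.update(overrides)
    return PopulationParams(**base)


@pytest.fixture(scope="session")
def template():
    return make_template()


@pytest.fixture(scope="session")
def population(template):
    """Default study-condition population: 68 cells digitised twice."""
    return simulate_population(template, seed=11)


@pytest.fixture(scope="session")
def small_population(template):
    """A cheap 10-cell population with default variance components."""
    return simulate_population(template, PopulationParams(n_cells=10), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
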