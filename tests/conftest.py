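import numpy as np
import pytest

from isomirome import SimulationConfig
from isomirome.pipeline import make_fixtures, run_on_fixtures
from isomirome.simulate import (
    generate_canonical_catalog,
    generate_cohort,
    generate_count_matrix,
    generate_isomir_repertoire,
)

DEFAULT_SEED = 0


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(rng_seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def catalog(sim_config):
    return generate_canonical_catalog(sim_config)


@pytest.fixture(scope="session")
def repertoire(sim_config, catalog):
    return generate_isomir_repertoire(catalog, sim_config)


@pytest.fixture(scope="session")
def cohort(sim_config):
    return generate_cohort(sim_config)


@pytest.fixture(scope="session")
def counts_and_truth(sim_config, repertoire, cohort):
    return generate_count_matrix(repertoire, cohort, sim_config)


@pytest.fixture(scope="session")
def fixture_paths(sim_config, tmp_path_factory):
    """The default 13-library synthetic dataset written to disk."""
    out = tmp_path_factory.mktemp("fixtures")
    return make_fixtures(sim_config, out)


@pytest.fixture(scope="session")
def default_result(fixture_paths):
    """One full pipeline run on the default fixture at study thresholds."""
    return run_on_fixtures(fixture_paths)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
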