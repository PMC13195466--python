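import pytest

from pfsmoke.fusion import run_fusion
from pfsmoke.grid import GridDefinition
from pfsmoke.synthetic import default_fixture


@pytest.fixture(scope="session")
def study():
    """The default desk-scale synthetic study (30x30 grid, 120 days)."""
    return default_fixture(seed=0)


@pytest.fixture(scope="session")
def fused(study):
    """Full fusion output on the default study."""
    return run_fusion(study.model_pair, study.observations, study.sites)


@pytest.fixture
def small_grid():
    return GridDefinition(n_rows=5, n_cols=5, cell_size_km=10.0)
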