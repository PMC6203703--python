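import numpy as np
import pytest

from climrefugia.pipeline import PipelineConfig, run_pipeline
from climrefugia.raster_core import GridSpec, RasterLayer
from climrefugia.synthetic_data import SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_bundle():
    """One seeded simulation under the default study conditions
    (60x60 grid, 6 variables, 10 species, 13 scenarios)."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(default_bundle):
    """Full pipeline run on the default fixture (shared across tests —
    the heavyweight computation happens once)."""
    b = default_bundle
    return run_pipeline(
        b.scenarios,
        b.occurrences,
        PipelineConfig(seed=1),
        bias=b.bias,
        reserves=b.reserves,
    )


@pytest.fixture
def small_grid():
    return GridSpec(n_rows=4, n_cols=5, x_origin=100.0, y_origin=20.0, cell_size=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_layer(grid, values, name=""):
    return RasterLayer(grid, np.asarray(values, dtype=float), name=name)
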