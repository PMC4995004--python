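import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from burstkit.benchmarks import benchmark_grid, clustering_grid
from burstkit.model_core import GridSpec, build_lookup_table

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_table():
    """Tiny grid containing the triples the unit tests sample from."""
    grid = GridSpec(
        k_on_values=np.array([0.5, 1.0, 1.1, 2.0, 4.0]),
        k_off_values=np.array([0.5, 1.0, 2.0, 4.0, 12.0]),
        k_t_values=np.array([5.0, 20.0, 50.0, 120.0]),
        x_max=200,
    )
    return build_lookup_table(grid)


@pytest.fixture(scope="session")
def bench_table():
    """Reduced estimation grid (25,000 triples) used by the benchmarks."""
    return build_lookup_table(benchmark_grid())


@pytest.fixture(scope="session")
def clust_table():
    """Coarse clustering grid (3,640 triples)."""
    return build_lookup_table(clustering_grid())
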