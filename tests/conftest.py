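import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "derandomized",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("derandomized")

from cnvpop import CohortSpec, simulate_cohort, simulate_genome


@pytest.fixture(scope="session")
def small_genome():
    """A 4-scaffold genome (~270 kb) with genes, reused across tests."""
    genome, features, go_map = simulate_genome(
        n_scaffolds=4, seed=11, mean_scaffold_length=60_000, gene_density=0.15
    )
    return genome, features, go_map


@pytest.fixture(scope="session")
def small_cohort(small_genome):
    """A 27-sample null cohort (11 vs 16) on the small genome."""
    genome, features, go_map = small_genome
    spec = CohortSpec(seed=101)
    _, _, _, truth, depths = simulate_cohort(
        spec, genome=genome, features=features, go_map=go_map
    )
    return genome, features, go_map, truth, depths


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
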