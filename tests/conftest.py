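import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pvgc import FamilySpec, Genome, random_genome, simulate_families

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20151016)


@pytest.fixture(scope="session")
def small_families():
    """Three small planted families (1.2 kb, 5% divergence) plus truth."""
    specs = [
        FamilySpec(ancestor_length=1200, n_members=3, divergence=0.05)
        for _ in range(3)
    ]
    return simulate_families(specs, seed=11)


@pytest.fixture
def toy_genome():
    return Genome(id="toy", sequence="ATGAAACCCGGGTTTTAA")


@pytest.fixture(scope="session")
def random_pair():
    a = random_genome(300, seed=101, genome_id="ra")
    b = random_genome(300, seed=102, genome_id="rb")
    return a, b
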