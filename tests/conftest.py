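import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_bundle():
    """One modest genome with three planted zero-divergence families."""
    from mitekit.simulate import FamilySpec, make_genome

    specs = [
        FamilySpec("BmMITE-2", "TGAGTCGACTATTATCAAAG", "TA/AT", 238, 5),
        FamilySpec("FAM-ATT", "GGTAGTTTTCCAATTACAG", "ATT", 180, 4),
        FamilySpec("FAM-N8", "CAAGGGCGGATCCAG", "NNNNNNNN", 233, 4),
    ]
    return make_genome(specs, gene_density=30, genome_length=80_000, seed=11)
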