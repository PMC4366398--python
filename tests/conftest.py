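import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sanctuary as sc

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def slow_sanctuary_model():
    """Two-compartment model with a slow sanctuary and near-critical drug side."""
    return sc.slow_sanctuary_model()


@pytest.fixture(scope="session")
def reference_landscape():
    """Constrained-pathway landscape with costly resistance (s=0.04, delta=0.22)."""
    return sc.PathwayLandscape(
        b00=0.5, d00=0.4, b10=0.48, d10=0.4, b01=0.39, d01=0.4, b11=0.45, d11=0.4
    )


@pytest.fixture(scope="session")
def resistance_mask():
    return sc.ResistantMask(genotype_min=1)


def random_small_model(rng):
    """A random well-posed model with n<=3 genotypes, M<=3 compartments."""
    n = rng.integers(2, 4)
    M = rng.integers(2, 4)
    birth = rng.uniform(0.05, 0.5, size=(n, M))
    death = np.tile(rng.uniform(0.05, 0.5, size=(1, M)), (n, 1))
    u = 10 ** rng.uniform(-3, -1)
    v = 10 ** rng.uniform(-3, -1)
    topology = "pairwise" if M == 2 else rng.choice(["ring", "global", "line"])
    return sc.build_model(
        sc.RateTable(birth=birth, death=death),
        sc.MutationSpec(u),
        sc.MigrationSpec(v, topology),
    )
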