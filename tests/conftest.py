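import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pollenclim as pc

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_percent_matrix(rng, n_rows=6, n_taxa=5, ids=None, taxa=None):
    """Random percent matrix with rows summing to exactly 100."""
    counts = rng.integers(1, 50, size=(n_rows, n_taxa)).astype(float)
    values = counts / counts.sum(axis=1, keepdims=True) * 100.0
    return pc.PollenMatrix(
        ids or [f"s{i}" for i in range(n_rows)],
        taxa or [f"t{j}" for j in range(n_taxa)],
        values, "percent",
    )


@pytest.fixture(scope="session")
def species_pool():
    return pc.make_species_pool(25, seed=11)


@pytest.fixture(scope="session")
def calset(species_pool):
    return pc.generate_calibration(species_pool, n_sites=60, seed=7)


@pytest.fixture(scope="session")
def calset_full(species_pool):
    """Full study-scale calibration set (133 sites)."""
    return pc.generate_calibration(species_pool, n_sites=133, seed=7)


@pytest.fixture(scope="session")
def modern_set(calset_full):
    return pc.apply_disturbance(calset_full, pc.DisturbanceScenario(), seed=13)
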