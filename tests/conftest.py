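import numpy as np
import pytest

from hrclassify.io import CountMatrix
from hrclassify.synthetic import RegionEffect, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 80-sample, 400-gene cohort with 45 planted effect genes."""
    cfg = SimulationConfig(
        n_samples=80,
        n_genes=400,
        n_excluded_genes=12,
        regions=(
            RegionEffect("8q24.2", 15, +1, log2fc_range=(1.0, 1.5)),
            RegionEffect("5q13.2", 15, -1, log2fc_range=(1.0, 1.5)),
            RegionEffect("19q12", 15, -1, log2fc_range=(1.0, 1.5)),
        ),
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def toy_counts():
    """Deterministic 5-gene x 4-sample matrix for arithmetic checks."""
    rng = np.random.default_rng(3)
    counts = rng.integers(0, 500, size=(5, 4))
    return CountMatrix([f"G{i}" for i in range(5)], [f"S{j}" for j in range(4)], counts)
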