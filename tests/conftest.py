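import numpy as np
import pandas as pd
import pytest

from pairsig.cohort import SimulationConfig, default_planted_pairs, generate_cohort
from pairsig.signature import load_signature


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_expr():
    """4 genes × 3 samples with known orderings (includes a tie in s3)."""
    return pd.DataFrame(
        {
            "s1": [5.0, 3.0, 1.0, 2.0],
            "s2": [1.0, 4.0, 2.0, 3.0],
            "s3": [3.0, 3.0, 5.0, 0.5],
        },
        index=["X", "Y", "Z", "W"],
    )


@pytest.fixture(scope="session")
def table2():
    return load_signature("table2")


@pytest.fixture(scope="session")
def planted_cohort():
    """120-sample cohort with one strong planted pair (MG0001|MG0002)."""
    config = SimulationConfig(
        n_samples=120,
        n_marker_genes=12,
        planted_pairs=default_planted_pairs(1, 1.0, n_marker_genes=12),
        censor_rate=0.25,
        seed=11,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effect: survival is independent of all pair indicators."""
    return generate_cohort(
        SimulationConfig(n_samples=150, n_marker_genes=10, censor_rate=0.3, seed=5)
    )


def random_survival(rng, n, censor_frac=0.0):
    """Tie-free random survival data, independent of any covariate."""
    time = rng.exponential(100.0, size=n)
    event = (rng.random(n) >= censor_frac).astype(int)
    return time, event
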