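import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import pcitnet as pn

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_counts() -> pn.CountMatrix:
    """4 genes x 6 samples (3 FH / 3 SFH) hand-written count matrix."""
    counts = pd.DataFrame(
        {
            "FH_1": [10, 100, 5, 0],
            "FH_2": [12, 90, 6, 0],
            "FH_3": [8, 110, 4, 0],
            "SFH_1": [40, 95, 5, 0],
            "SFH_2": [38, 105, 6, 0],
            "SFH_3": [42, 100, 4, 0],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    groups = pd.Series(
        ["FH", "FH", "FH", "SFH", "SFH", "SFH"], index=counts.columns
    )
    return pn.CountMatrix(counts=counts, groups=groups)


@pytest.fixture
def sim_small():
    """Deterministic 200-gene simulation with 20 planted DEGs."""
    config = pn.SimConfig(
        n_genes=200, n_samples_per_group=(8, 7), n_deg=20, lfc_magnitude=2.0,
        nb_dispersion=0.05, seed=7,
    )
    return pn.simulate_counts(config)


def random_correlation(rng: np.random.Generator, p: int, n: int) -> np.ndarray:
    """A valid sample correlation matrix from random Gaussian data."""
    return pn.pearson_matrix(rng.standard_normal((p, n)))
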