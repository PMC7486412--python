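import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import germdiv as gd

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_collection() -> gd.SyntheticCollection:
    """Three drifted subpopulations, 50 samples each, 5% missing calls."""
    spec = gd.PopulationSpec(
        n_subpops=3, samples_per_subpop=[50, 50, 50], n_loci=600,
        drift_f=0.2, missing_rate=0.05, seed=11,
    )
    return gd.simulate_structured_snps(spec)


@pytest.fixture(scope="session")
def complete_collection() -> gd.SyntheticCollection:
    """Two subpopulations, no missing data (for metric/embedding checks)."""
    spec = gd.PopulationSpec(
        n_subpops=2, samples_per_subpop=[30, 30], n_loci=400,
        drift_f=0.15, missing_rate=0.0, seed=7,
    )
    return gd.simulate_structured_snps(spec)


@pytest.fixture
def tiny_geno() -> gd.GenotypeMatrix:
    """Five samples x four markers, hand-written with a missing call."""
    dosage = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 0, 0],
            [2, 0, 1, 0],
            [0, 2, 2, 0],
            [1, np.nan, 0, 0],
        ],
        dtype=float,
    )
    return gd.GenotypeMatrix(
        [f"S{i}" for i in range(5)], [f"M{j}" for j in range(4)], dosage
    )


def euclidean_distance_matrix(points: np.ndarray) -> gd.DistanceMatrix:
    from scipy.spatial.distance import pdist, squareform

    vals = squareform(pdist(points))
    return gd.DistanceMatrix([f"P{i}" for i in range(len(points))], vals, "MRD")
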