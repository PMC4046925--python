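import numpy as np
import pandas as pd
import pytest

from succession import (
    AbundanceTable,
    CohortSpec,
    SampleMetadata,
    generate_cohort,
    generate_function_table,
    random_function_map,
)


@pytest.fixture(scope="session")
def cohort():
    """Full-design synthetic cohort: 13 pairs, 7 timepoints, 9 I2 samples."""
    spec = CohortSpec(seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort for fast tests."""
    spec = CohortSpec(
        n_pairs=6,
        n_genera=30,
        n_core_genera=5,
        richness_trajectory={"I1": 10, "I2": 14, "I3": 20, "I4": 13, "I5": 16, "MA": 24, "MB": 22},
        reads_per_sample=(3000, 6000),
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def function_table(cohort):
    taxa, _ = cohort
    fmap = random_function_map(taxa.feature_ids, seed=21)
    return generate_function_table(taxa, fmap, seed=22), fmap


def random_table(rng, n_features=50, n_samples=20, max_count=200) -> AbundanceTable:
    counts = rng.integers(0, max_count, size=(n_features, n_samples))
    counts[0] += 1  # guarantee nonzero sample totals
    return AbundanceTable(
        pd.DataFrame(
            counts,
            index=[f"f{i}" for i in range(n_features)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )
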