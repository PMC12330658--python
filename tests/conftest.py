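import numpy as np
import pandas as pd
import pytest

from tadard import (SimulatedCohortConfig, generate_labeled_table,
                    train_classdn, score_variants)


@pytest.fixture(scope="session")
def labeled_cohort() -> pd.DataFrame:
    """Default family-style labeled cohort (seed 0)."""
    return generate_labeled_table(SimulatedCohortConfig(rng_seed=0))


@pytest.fixture(scope="session")
def train_test_tables():
    """Two independent labeled cohorts for fitting and evaluation."""
    train = generate_labeled_table(
        SimulatedCohortConfig(n_genes=400, n_variants_total=12_000, rng_seed=101))
    test = generate_labeled_table(
        SimulatedCohortConfig(n_genes=400, n_variants_total=12_000, rng_seed=202))
    return train, test


@pytest.fixture(scope="session")
def fitted_rusboost(train_test_tables):
    train, test = train_test_tables
    model = train_classdn(train, algorithm="rusboost", rng_seed=7)
    scores = score_variants(model, test)
    return model, test, scores
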