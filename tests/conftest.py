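import numpy as np
import pandas as pd
import pytest

from osteocoupling import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_study():
    """A small default-parameter cohort shared across read-only tests."""
    return simulate_cohort(CohortConfig(n_genes=500, seed=11))


@pytest.fixture(scope="session")
def default_study():
    """A full-size cohort at the study's default scale."""
    return simulate_cohort(CohortConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_counts(values, gene_ids=None, sample_ids=None):
    values = np.asarray(values)
    genes = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    samples = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)
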