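import numpy as np
import pandas as pd
import pytest

from covariome.containers import AbundanceMatrix
from covariome.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The full-scale default synthetic cohort (50 samples, 2000 proteins)."""
    return generate_cohort(CohortSpec(seed=1))


SMALL_SPEC = CohortSpec(
    seed=1, n_proteins=700, n_complexes=20, n_lof_genes=15,
    n_subtypes=5, subtype_block_size=30,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for unit tests (700 proteins, same structure)."""
    return generate_cohort(SMALL_SPEC)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_matrix(values, features=None, samples=None, like_intensities=False):
    values = np.asarray(values, dtype=float)
    features = features or [f"F{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    if like_intensities:
        values = np.power(2.0, values) * 100.0
    return AbundanceMatrix(pd.DataFrame(values, index=features, columns=samples))
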