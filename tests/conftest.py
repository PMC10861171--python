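import numpy as np
import pytest

import connweight as cw


@pytest.fixture(scope="session")
def small_config():
    return cw.CohortConfig(
        n_subjects=12, nodes_per_hemisphere=14, streamline_budget=4000, seed=7
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    atlas, tables = cw.generate_cohort(small_config)
    return atlas, tables


def symmetric_matrix(rng, n, density=0.4, kind="NOS", integer=False):
    """Random symmetric nonnegative matrix with zero diagonal."""
    w = rng.random((n, n)) * (rng.random((n, n)) < density)
    if integer:
        w = np.ceil(w * 5)
    w = np.triu(w, k=1)
    w = w + w.T
    return cw.ConnectivityMatrix(w, kind=kind, provenance="test")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
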