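import numpy as np
import pytest

import rehabfuse as rf


@pytest.fixture(scope="session")
def tiny_dataset():
    """Six-subject dataset with recordings and labels (shared, read-only)."""
    return rf.generate_dataset(rf.CohortConfig(n_subjects=6), seed=42)


@pytest.fixture(scope="session")
def tiny_tables(tiny_dataset):
    return rf.build_feature_tables(tiny_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
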