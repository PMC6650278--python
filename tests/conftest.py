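import numpy as np
import pandas as pd
import pytest

from dysbiokit.profiles import AbundanceTable
from dysbiokit.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact mixed-diagnosis cohort reused across read-only tests."""
    cfg = CohortConfig(
        n_subjects_per_group={"nonIBD": 12, "UC": 6, "CD": 6}, seed=7
    )
    return simulate_cohort(cfg)


@pytest.fixture
def tiny_table():
    """3 features x 2 samples with simple values."""
    data = pd.DataFrame(
        {"s1": [2.0, 2.0, 4.0], "s2": [1.0, 0.0, 3.0]},
        index=["f1", "f2", "f3"],
    )
    return AbundanceTable(data, "other")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
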