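import numpy as np
import pandas as pd
import pytest

from costlab.catalog import load_default_catalog
from costlab.cohort import default_config, generate_cohort


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """Mid-size calibrated cohort shared across model tests."""
    return generate_cohort(default_config(n=4000, seed=7))


@pytest.fixture(scope="session")
def default_cohort_987():
    """One cohort at the study's sample size, default seed."""
    return generate_cohort(default_config(n=987, seed=0))


@pytest.fixture()
def toy_cost_frame():
    """Six-record cohort small enough to verify OLS/smearing by hand."""
    return pd.DataFrame(
        {
            "cost_total": [1000.0, 1500.0, 2200.0, 3000.0, 4500.0, 6000.0],
            "exposed": [0, 0, 0, 1, 1, 1],
            "age": [60.0, 70.0, 80.0, 62.0, 71.0, 79.0],
        }
    )


def rng(seed=0):
    return np.random.default_rng(seed)
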