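import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from frailtyindex import load_packaged_schema

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def nshs_schema():
    return load_packaged_schema("nshs", "corrected")


@pytest.fixture(scope="session")
def share_schema():
    return load_packaged_schema("share", "corrected")


@pytest.fixture(scope="session")
def yale_schema():
    return load_packaged_schema("yale_pep", "corrected")


@pytest.fixture()
def rng():
    return np.random.default_rng(870223)


def random_deficit_matrix(rng, n, k, missing_rate=0.2):
    """Random values in [0,1] with NaN holes, as a DataFrame."""
    vals = rng.random((n, k))
    mask = rng.random((n, k)) < missing_rate
    vals[mask] = np.nan
    return pd.DataFrame(vals, columns=[f"item_{j}" for j in range(k)])
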