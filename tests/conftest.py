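import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from plawcorrect import CountMatrix, SimSpec, make_series, zipf_library

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_matrix():
    """3 transcripts x 2 samples, hand-checkable."""
    df = pd.DataFrame(
        {"s1": [10, 5, 1], "s2": [7, 0, 3]}, index=["t1", "t2", "t3"]
    )
    return CountMatrix(df)


@pytest.fixture(scope="session")
def dilution_series():
    """One simulated dilution series shared across tests (seed 0)."""
    lib = zipf_library(1000, 1.0)
    return make_series(SimSpec(library=lib, seed=0))


def make_random_counts(rng, n_transcripts=40, n_samples=4, zeros=True):
    counts = rng.integers(0 if zeros else 1, 500, size=(n_transcripts, n_samples))
    counts[0] = counts[0] + 1  # keep every sample non-all-zero
    df = pd.DataFrame(
        counts,
        index=[f"t{i}" for i in range(n_transcripts)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return CountMatrix(df)
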