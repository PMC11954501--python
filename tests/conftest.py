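import numpy as np
import pytest

from nmalab import ContrastRecord, McmcConfig, build_network


@pytest.fixture
def quick_mcmc():
    """A short schedule for unit tests; full-scale runs live in the
    acceptance suite."""
    return McmcConfig(n_burn=1000, n_sample=4000, n_chains=4, seed=11)


@pytest.fixture
def triangle_records():
    """Three two-arm trials forming a closed A-B-C loop, all null effects."""
    return [
        ContrastRecord("t1", "os", "B", "A", 0.0, 0.1),
        ContrastRecord("t2", "os", "C", "B", 0.0, 0.1),
        ContrastRecord("t3", "os", "C", "A", 0.0, 0.1),
    ]


@pytest.fixture
def triangle(triangle_records):
    return build_network(triangle_records, "os", "A")


@pytest.fixture
def two_trial_records():
    """Two trials of the same comparison: the inverse-variance pooling
    oracle gives mean 0.24, SE 0.0894."""
    return [
        ContrastRecord("t1", "os", "B", "A", 0.2, 0.1),
        ContrastRecord("t2", "os", "B", "A", 0.4, 0.2),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
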