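import numpy as np
import pytest

from peanutstore import synthetic
from peanutstore.synthetic import KineticParams


@pytest.fixture(scope="session")
def default_table():
    """210-day, 3-condition table with default kinetics and noise."""
    return synthetic.simulate_storage(n_days=210)


@pytest.fixture(scope="session")
def noiseless_params():
    return KineticParams(noise_sd={k: 0.0 for k in KineticParams().noise_sd})


@pytest.fixture(scope="session")
def noiseless_table(noiseless_params):
    return synthetic.simulate_storage(params=noiseless_params, n_days=210)


@pytest.fixture(scope="session")
def blob_5():
    """Well-separated 5-cluster fixture on the grade profiles."""
    return synthetic.make_blob_fixture(k=5, n_per_cluster=40, separation=10.0,
                                       seed=7)


@pytest.fixture(scope="session")
def blob_3():
    return synthetic.make_blob_fixture(k=3, n_per_cluster=40, separation=10.0,
                                       seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
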