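import numpy as np
import pytest

import corrdelta as cd


@pytest.fixture(scope="session")
def host():
    return cd.load_host_constants()


@pytest.fixture(scope="session")
def cv1_joint():
    return cd.build_joint(cd.deb_parameter_scenario("CV1"))


@pytest.fixture(scope="session")
def linear_indep():
    """Worked linear benchmark, independent inputs, moderate n."""
    return cd.linear_benchmark(20_000, seed=101, independent=True)


@pytest.fixture(scope="session")
def linear_corr():
    """Worked linear benchmark with corr(X1, X4) = 0.9."""
    return cd.linear_benchmark(20_000, seed=101, independent=False)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
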