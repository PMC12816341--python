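import numpy as np
import pytest

import bim


@pytest.fixture(scope="session")
def unidir_model():
    """Closed-form benchmark: Y1 white, Y2_n = Y1_{n-1} + U2, unit variances."""
    return bim.benchmark_unidirectional(c=1.0).model


@pytest.fixture(scope="session")
def unidir_pair():
    spec = bim.benchmark_unidirectional(c=1.0, L=4096, seed=42)
    return bim.simulate_arx(spec)


@pytest.fixture(scope="session")
def independent_pair():
    """Two independent white-noise series."""
    rng = np.random.default_rng(7)
    return bim.TimeSeriesPair(rng.standard_normal(2048), rng.standard_normal(2048))


def linear_t12(pair, p=2, q=20):
    """Linear transfer entropy 1 -> 2 via OLS + Yule-Walker restriction."""
    arx = bim.identify_arx(pair, p)
    r2 = bim.restrict_yw(arx, 2, q)
    return 0.5 * float(np.log(r2.lambda2 / arx.Sigma_U[1, 1]))
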