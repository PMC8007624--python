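import numpy as np
import pytest

import oifnet as o


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plain_config():
    """Estimator config with no bias corrections: pure plug-in values."""
    return o.EstimatorConfig(te_correction="none", mi_correction="none")


@pytest.fixture(scope="session")
def chaotic_pair():
    """Unidirectionally coupled logistic pair S(0, 0.8), 1000 retained steps."""
    ts = o.simulate_coupled_logistic(
        o.CoupledLogisticParams(beta_yx=0.8, n_steps=1000)
    )
    return ts.series("X"), ts.series("Y")


@pytest.fixture(scope="session")
def community():
    """Default seeded 15-species community with ground truth."""
    return o.simulate_community(o.maizuru_like_params(seed=0))
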