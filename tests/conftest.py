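import numpy as np
import pytest

from armreach import (ArmParameters, OCPSettings, OCPTask, ScalarFactors,
                      WeightVector, single_cost_solutions, solve_ocp)
from armreach.ioc import calibrate_scalar_factors


@pytest.fixture(scope="session")
def params():
    return ArmParameters()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def smoke_task():
    """A mid-workspace reach used by the slower optimal-control tests."""
    qs = np.deg2rad([10.0, 10.0, 60.0])
    qe = np.deg2rad([30.0, 50.0, 10.0])
    return OCPTask(tuple(qs), tuple(qe), 1.0, n_nodes=30)


@pytest.fixture(scope="session")
def fast_ocp_settings():
    return OCPSettings(n_basis=5, max_iter=150)


@pytest.fixture(scope="session")
def smoke_singles(smoke_task, params, fast_ocp_settings):
    """Shared one-hot solutions for the smoke task (5 OCP solves)."""
    return single_cost_solutions(smoke_task, params, fast_ocp_settings)


@pytest.fixture(scope="session")
def smoke_scalar_factors(smoke_task, params, fast_ocp_settings, smoke_singles):
    return calibrate_scalar_factors(smoke_task, params, fast_ocp_settings,
                                    _solutions=smoke_singles)


def random_admissible_q(params, rng, n=1, margin=0.05):
    lo = np.asarray(params.q_min)
    hi = np.asarray(params.q_max)
    span = hi - lo
    q = rng.uniform(lo + margin * span, hi - margin * span, size=(n, 3))
    return q[0] if n == 1 else q
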