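import numpy as np
import pytest

from mepsim.synthetic_data import ErrorModelSpec, make_scenario
from mepsim.transforms import PreparedDesign


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sim1_scenario():
    return make_scenario("sim1")


@pytest.fixture
def identity_spec():
    """Classical additive two-component spec with small variances."""
    return ErrorModelSpec(
        p=2, q=0, lambda_bc=np.ones(2), beta0=np.array([10.0, 12.0]),
        betaZ=np.zeros((2, 0)),
        Sigma_u=np.array([[1.0, 0.3], [0.3, 0.8]]),
        Sigma_eps=np.array([[0.5, 0.1], [0.1, 0.4]]),
        observation="identity",
    )


def toy_design(M, columns=None, strategy="average", k_used=1):
    M = np.asarray(M, dtype=float)
    cols = columns or [f"x{i + 1}" for i in range(M.shape[1])]
    return PreparedDesign(M=M, columns=cols, strategy=strategy, k_used=k_used)
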