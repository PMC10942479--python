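import numpy as np
import pytest

from ecocavity.systems import CRMSystem


@pytest.fixture
def macarthur_pair() -> CRMSystem:
    """Two species competing for two self-renewing resources; the classic
    worked example whose equilibrium is the minimizer of the quadratic
    objective (r_a = m_i = w_a = 1, K = (4.8, 2.85))."""
    return CRMSystem(
        c=[[0.5, 0.3], [0.4, 0.6]],
        m=[1.0, 1.0],
        kind="self_renewing",
        K=[4.8, 2.85],
        r_res=[1.0, 1.0],
    )


@pytest.fixture
def macarthur_pair_oracle():
    """Independent linear-solve oracle for the fixture above: survivors'
    resource state solves c'R = m, then K - R gives the abundances."""
    c = np.array([[0.5, 0.3], [0.4, 0.6]])
    K = np.array([4.8, 2.85])
    R = np.linalg.solve(c, np.ones(2))
    # resource equilibrium with r = 1: R = K (1 - c'N)  =>  c'N = 1 - R/K
    N = np.linalg.solve(c.T, 1.0 - R / K)
    return N, R
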