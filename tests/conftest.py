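import numpy as np
import pytest

from patchsde import TwoPatchSpec, fixture_spec, make_two_patch


@pytest.fixture
def sweep_rho0():
    return fixture_spec("two_patch_sweep", rho=0.0, alpha=1.0)


@pytest.fixture
def sweep_rho1():
    return fixture_spec("two_patch_sweep", rho=1.0, alpha=1.0)


@pytest.fixture
def degenerate_unequal():
    # perfectly correlated noise with unequal volatilities (rank-one Sigma)
    return TwoPatchSpec(a1=3.0, a2=4.0, d12=1.0, d21=1.0,
                        sigma1=3.0, sigma2=1.0, rho=1.0)


@pytest.fixture
def sweep_model(sweep_rho0):
    return make_two_patch(sweep_rho0)
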