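import numpy as np
import pytest

import neurofrag as nf


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def half_reset_kernel():
    """Proportional reset psi(u) = u/2 (theta = 1/2)."""
    return nf.FragmentationKernel.point_map_linear(0.5)


@pytest.fixture(scope="session")
def full_reset_kernel():
    """Classical age-structured reset K = delta_{s=0}."""
    return nf.FragmentationKernel.full_reset()


@pytest.fixture(scope="session")
def constant_rate():
    """p identically 1 (no refractory period, ceiling 1)."""
    return nf.FiringRate(family="regularized", threshold=0.0, pM=1.0)


@pytest.fixture(scope="session")
def weak_coupling_setup():
    """Regularized short-refractory configuration with B* < 1.

    Constant threshold sigma = 0.3, ramp width 0.2, ceiling 1, kernel
    psi(u) = u/2: the smallness certificate applies and the dynamics is
    linear (rate independent of N).
    """
    rate = nf.FiringRate(
        family="regularized", threshold=0.3, pM=1.0, smoothing_width=0.2
    )
    kern = nf.FragmentationKernel.point_map_linear(0.5)
    return rate, kern
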