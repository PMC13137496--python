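import numpy as np
import pytest

from dtialps import (
    FiberPopulation,
    NoiseModel,
    PhantomConfig,
    build_alps_phantom,
    make_gradient_table,
    simulate_voxel_signal,
)
from dtialps.fod import estimate_response


@pytest.fixture(scope="session")
def paper_gtab():
    """The study's four-shell acquisition scheme."""
    return make_gradient_table("paper")


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default-geometry ALPS phantom without measurement noise."""
    return build_alps_phantom(PhantomConfig(noise=NoiseModel("none")))


@pytest.fixture(scope="session")
def snr30_phantom():
    """Default ALPS phantom at Rician SNR 30."""
    return build_alps_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def wm_response(paper_gtab):
    """Single-fibre response estimated from an analytic z-aligned fibre."""
    pop = [FiberPopulation([0.0, 0.0, 1.0], 1.0, 1.7e-3, 0.3e-3)]
    sig = simulate_voxel_signal(pop, 0.0, np.zeros((3, 3)), paper_gtab, 100.0)
    return estimate_response(sig[None, :], np.array([[0.0, 0.0, 1.0]]), paper_gtab, lmax=8, shell_b=2000.0)
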