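import numpy as np
import pytest

import acdcmotif as ac


@pytest.fixture(scope="session")
def fig2a():
    return ac.load_preset("fig2a")


@pytest.fixture(scope="session")
def fig2b():
    return ac.load_preset("fig2b")


@pytest.fixture(scope="session")
def fig3a():
    return ac.load_preset("fig3a")


@pytest.fixture(scope="session")
def fig3b():
    return ac.load_preset("fig3b")


@pytest.fixture(scope="session")
def sampled_params():
    """A reusable batch of validity-passing random parameter sets."""
    return ac.sample_parameters(40, seed=11)


@pytest.fixture(scope="session")
def fig2b_cycle(fig2b):
    """A converged limit-cycle trajectory, shared across tests."""
    return ac.integrate(fig2b, 1.7, t_end=500.0)
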