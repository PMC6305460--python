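import numpy as np
import pytest

from neuroforward.cable import PassiveParams, SynapseSpec, simulate
from neuroforward.morphology import (Section, discretize, make_ball_and_stick,
                                     make_stylized_pyramidal)


@pytest.fixture(scope="session")
def ball_and_stick():
    return make_ball_and_stick(20.0, 400.0, 2.0, nseg=8)


@pytest.fixture(scope="session")
def pyramidal():
    return make_stylized_pyramidal(seed=1)


@pytest.fixture(scope="session")
def passive():
    return PassiveParams()


@pytest.fixture(scope="session")
def single_compartment():
    sec = Section(0, "soma", np.array([[0.0, 0, -10], [0, 0, 10.0]]),
                  np.full(2, 20.0), parent=None, nseg=1)
    return discretize([sec])


@pytest.fixture(scope="session")
def bs_synaptic_sim(ball_and_stick, passive):
    """Ball-and-stick with one apical synapse activated at t = 2 ms."""
    syn = SynapseSpec(segment=8, onsets=(2.0,), tau_r=0.2, tau_d=1.7,
                      g_max=1.0, e_syn=0.0)
    return simulate(ball_and_stick, passive, synapses=[syn], T=30.0)


@pytest.fixture(scope="session")
def bs_soma_sim(ball_and_stick, passive):
    """Ball-and-stick driven at the proximal stick (compact current
    distribution, suited to far-field dipole comparisons)."""
    syn = SynapseSpec(segment=1, onsets=(2.0,), tau_r=0.2, tau_d=1.7,
                      g_max=1.0, e_syn=0.0)
    return simulate(ball_and_stick, passive, synapses=[syn], T=60.0)


@pytest.fixture(scope="session")
def pyr_synaptic_sim(pyramidal, passive):
    """Stylized pyramidal with a synapse at the top of the apical trunk."""
    trunk = np.flatnonzero(pyramidal.section_id == 1)
    syn = SynapseSpec(segment=int(trunk[-1]), onsets=(2.0,),
                      tau_r=0.2, tau_d=1.7, g_max=2.0, e_syn=0.0)
    return simulate(pyramidal, passive, synapses=[syn], T=30.0)
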