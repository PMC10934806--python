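import numpy as np
import pytest

from conformetrics import synthetic as syn
from conformetrics.structio import Trajectory


@pytest.fixture(scope="session")
def ab42_topology():
    return syn.monomer_topology(syn.AB42_SEQUENCE)


@pytest.fixture(scope="session")
def helix_traj(ab42_topology):
    return Trajectory(
        topology=ab42_topology, coords=syn.helix_frame(syn.AB42_SEQUENCE)[None]
    )


@pytest.fixture(scope="session")
def extended_traj(ab42_topology):
    return Trajectory(
        topology=ab42_topology, coords=syn.extended_frame(syn.AB42_SEQUENCE)[None]
    )


@pytest.fixture(scope="session")
def hairpin_traj(ab42_topology):
    return Trajectory(
        topology=ab42_topology, coords=syn.hairpin_frame(syn.AB42_SEQUENCE)[None]
    )


@pytest.fixture(scope="session")
def static_fibril():
    """Noise-free 10-strand stack at 4.8 A rise, no fan, no dissociation."""
    traj, log = syn.make_fibril(syn.FibrilSpec(n_frames=3))
    return traj


@pytest.fixture(scope="session")
def antiparallel_sheet():
    return syn.make_antiparallel_sheet()
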