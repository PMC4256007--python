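"""Shared fixtures: small synthetic systems reused across test modules."""

import numpy as np
import pytest

from npmem import synth
from npmem.traj_io import Box, Frame, Topology, Trajectory


@pytest.fixture(scope="session")
def small_bilayer():
    """A 200-lipid, 20% cholesterol bilayer with 3 frames."""
    spec = synth.BilayerSpec(n_lipids=200, chol_fraction=0.2)
    return synth.gen_bilayer(spec, seed=11, n_frames=3)


@pytest.fixture(scope="session")
def bilayer_with_np(small_bilayer):
    """The small bilayer with a reduced nanoparticle embedded mid-membrane."""
    traj, top = small_bilayer
    np_spec = synth.NPSpec(
        core_diameter=2.0, n_mus=20, n_ot=10, mus_length_beads=3, ot_length_beads=2
    )
    center = (traj.box.lx / 2, traj.box.ly / 2, traj.box.lz / 2)
    pos, np_top = synth.gen_np(np_spec, seed=12, center=center)
    return synth.combine(traj, top, pos, np_top)


@pytest.fixture()
def toy_frame():
    """Ten beads on a line in a 10 nm box, one molecule each."""
    pos = np.zeros((10, 3))
    pos[:, 0] = np.linspace(1.0, 9.0, 10)
    pos[:, 2] = 5.0
    box = Box(10.0, 10.0, 10.0)
    top = Topology.from_arrays(
        molecule_id=np.arange(10),
        species=["DPPC"] * 10,
        role=["tail"] * 10,
    )
    return Frame(0.0, pos, box), top
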