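import numpy as np
import pytest

from brushsim.energetics import ParticleSystem
from brushsim.model import InteractionTable, SimulationParameters


@pytest.fixture
def table2():
    """Default interaction table for one brush population."""
    return InteractionTable.default(1)


@pytest.fixture
def params():
    return SimulationParameters()


def random_system(n, rng, box_xy=(7.0, 7.0), h=8.0, with_chain=False):
    """A randomized small system; optionally the first 5 particles form a
    bonded chain (species 1), the rest are solvent."""
    pos = rng.random((n, 3)) * np.array([box_xy[0], box_xy[1], h])
    species = np.zeros(n, dtype=np.int64)
    bonds = np.zeros((0, 2), dtype=np.int64)
    kap = np.zeros(0)
    r0 = np.zeros(0)
    chain_id = np.full(n, -1, dtype=np.int64)
    if with_chain and n >= 5:
        species[:5] = 1
        bonds = np.array([[i, i + 1] for i in range(4)], dtype=np.int64)
        kap = np.full(4, 100.0)
        r0 = np.zeros(4)
        chain_id[:5] = 0
        # keep chain bonds short so energies stay moderate
        for k in range(1, 5):
            pos[k] = pos[k - 1] + rng.normal(0, 0.15, 3)
        pos[:5, 2] = np.clip(pos[:5, 2], 0.0, h)
    return ParticleSystem(
        positions=pos, species=species, bonds=bonds, bond_kappa=kap,
        bond_r0=r0, graft=np.zeros(n, dtype=np.int64), chain_id=chain_id,
        box_xy=box_xy, h=h)
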