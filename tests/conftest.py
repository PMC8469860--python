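import numpy as np
import pytest

from gelblend.forcefield import ForceField, default_forcefield
from gelblend.system import ParticleSystem


@pytest.fixture(scope="session")
def ff():
    return default_forcefield(cutoff=7.0)


@pytest.fixture
def bare_ff():
    """Bonds-only force field (nonbonded disabled)."""
    return ForceField(lj={"C": (0.0, 0.5), "N": (0.0, 0.5),
                          "O": (0.0, 0.5), "H": (0.0, 0.5)},
                      cutoff=2.0, coulomb=False)


def make_atoms(positions, elements=None, masses=None, charges=None,
               bonds=None, bond_k=10.0, bond_r0=1.0, cell=None,
               species="gelatin"):
    """Small hand-built systems for engine tests."""
    positions = np.asarray(positions, float)
    n = len(positions)
    elements = np.array(elements or ["C"] * n)
    masses = np.asarray(masses if masses is not None else np.ones(n), float)
    charges = np.asarray(charges if charges is not None else np.zeros(n),
                         float)
    b = np.asarray(bonds if bonds is not None else [], int).reshape(-1, 2)
    return ParticleSystem(
        positions=positions, masses=masses, charges=charges,
        elements=elements, names=np.array(["X"] * n),
        species=np.array([species] * n), molecule_id=np.zeros(n, int),
        bonds=b, bond_k=np.full(len(b), float(bond_k)),
        bond_r0=np.full(len(b), float(bond_r0)),
        cell=None if cell is None else np.diag(np.asarray(cell, float)))


@pytest.fixture
def make_system():
    return make_atoms
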