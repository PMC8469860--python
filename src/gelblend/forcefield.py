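"""Class-I force field: harmonic bonds/angles, cosine dihedrals,
Lennard-Jones and shifted-force Coulomb with a global cutoff.

Bonded equilibrium values live on the system (resolved from the
templates at build time); this object holds the nonbonded tables and the
cutoff.  Parameters are a generic set for united-atom C plus explicit
polar H on N/O — magnitudes give realistic cohesion and stiffness
trends, not any specific published material's absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# per-element Lennard-Jones parameters: (epsilon kcal/mol, sigma Å)
DEFAULT_LJ = {
    "C": (0.10, 3.80),
    "N": (0.17, 3.30),
    "O": (0.17, 3.10),
    "H": (0.01, 1.00),
}


@dataclass
class ForceField:
    lj: dict = field(default_factory=lambda: dict(DEFAULT_LJ))
    cutoff: float = 7.0          # Å, shared by LJ and Coulomb
    coulomb: bool = True
    dielectric: float = 1.0

    def __post_init__(self):
        for el, (eps, sig) in self.lj.items():
            if eps < 0 or sig <= 0:
                raise ValueError(f"invalid LJ parameters for {el}")
        if self.cutoff <= max(s for _, s in self.lj.values()):
            raise ValueError("cutoff must exceed the largest sigma")

    def lj_tables(self, elements: np.ndarray):
        """Per-atom epsilon and sigma arrays (Lorentz–Berthelot mixing is
        applied pairwise by the engine)."""
        eps = np.array([self.lj[e][0] for e in elements])
        sig = np.array([self.lj[e][1] for e in elements])
        return eps, sig


def default_forcefield(cutoff: float = 7.0) -> ForceField:
    return ForceField(cutoff=cutoff)
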