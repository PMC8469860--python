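"""Central molecular state: particles, topology and the periodic cell.

A :class:`ParticleSystem` holds positions/velocities/masses/charges,
species labels (``gelatin`` / ``pva``) and the bonded topology with the
parameters already resolved onto each term.  Fragments produced by the
builder carry ``cell=None``; packed cells carry a 3×3 cell matrix
(orthorhombic in practice, slightly triclinic under applied shear
strain).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import LabelingError


@dataclass
class ParticleSystem:
    positions: np.ndarray                       # (N, 3) Å
    masses: np.ndarray                          # (N,) amu
    charges: np.ndarray                         # (N,) e
    elements: np.ndarray                        # (N,) str, 'C'/'N'/'O'/'H'
    names: np.ndarray                           # (N,) str atom names
    species: np.ndarray                         # (N,) str parent species
    molecule_id: np.ndarray                     # (N,) int
    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))
    bond_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bond_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), int))
    angle_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angle_theta0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dihedrals: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), int))
    dihedral_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dihedral_n: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    dihedral_phi0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    velocities: np.ndarray | None = None        # (N, 3) Å/fs
    cell: np.ndarray | None = None              # (3, 3) Å, rows are cell vectors

    def __post_init__(self):
        n = len(self.positions)
        if self.velocities is None:
            self.velocities = np.zeros((n, 3))
        for arr, name in [(self.masses, "masses"), (self.charges, "charges"),
                          (self.elements, "elements"), (self.names, "names"),
                          (self.species, "species"),
                          (self.molecule_id, "molecule_id")]:
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        self._exclusions = None

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    @property
    def box_lengths(self) -> np.ndarray:
        if self.cell is None:
            raise ValueError("fragment has no periodic cell")
        return np.linalg.norm(self.cell, axis=1)

    @property
    def volume(self) -> float:
        if self.cell is None:
            raise ValueError("fragment has no periodic cell")
        return float(abs(np.linalg.det(self.cell)))

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            positions=self.positions.copy(),
            masses=self.masses.copy(),
            charges=self.charges.copy(),
            elements=self.elements.copy(),
            names=self.names.copy(),
            species=self.species.copy(),
            molecule_id=self.molecule_id.copy(),
            bonds=self.bonds.copy(), bond_k=self.bond_k.copy(),
            bond_r0=self.bond_r0.copy(),
            angles=self.angles.copy(), angle_k=self.angle_k.copy(),
            angle_theta0=self.angle_theta0.copy(),
            dihedrals=self.dihedrals.copy(), dihedral_k=self.dihedral_k.copy(),
            dihedral_n=self.dihedral_n.copy(),
            dihedral_phi0=self.dihedral_phi0.copy(),
            velocities=self.velocities.copy(),
            cell=None if self.cell is None else self.cell.copy(),
        )

    # ------------------------------------------------------------------
    def bonded_adjacency(self) -> list[set]:
        adj = [set() for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[i].add(int(j))
            adj[j].add(int(i))
        return adj

    def exclusion_pairs(self) -> set:
        """1-2 and 1-3 pairs (sorted tuples) excluded from nonbonded sums."""
        if self._exclusions is not None:
            return self._exclusions
        adj = self.bonded_adjacency()
        excl = set()
        for i, j in self.bonds:
            excl.add((min(i, j), max(i, j)))
        for j, neigh in enumerate(adj):
            ns = sorted(neigh)
            for a in range(len(ns)):
                for b in range(a + 1, len(ns)):
                    excl.add((ns[a], ns[b]))
        self._exclusions = excl
        return excl

    def invalidate_topology_cache(self):
        self._exclusions = None

    def wrap(self):
        """Wrap coordinates into the primary cell, [0, L) per axis."""
        if self.cell is None:
            return
        h = self.cell.T
        frac = np.linalg.solve(h, self.positions.T).T
        frac -= np.floor(frac)
        self.positions = frac @ self.cell

    def remove_net_charge(self):
        """Spread any residual net charge uniformly (cutoff electrostatics
        on neutral species)."""
        if self.n_atoms:
            self.charges = self.charges - self.charges.mean()

    def species_mask(self, name: str) -> np.ndarray:
        if not np.all(np.isin(self.species, ["gelatin", "pva"])):
            raise LabelingError("atoms carry unknown species labels")
        return self.species == name


def concatenate(fragments: list[ParticleSystem]) -> ParticleSystem:
    """Merge fragments into one system, offsetting topology indices."""
    offset = 0
    mol_offset = 0
    pieces = {k: [] for k in ["positions", "masses", "charges", "elements",
                              "names", "species", "molecule_id", "velocities"]}
    topo = {k: [] for k in ["bonds", "bond_k", "bond_r0", "angles", "angle_k",
                            "angle_theta0", "dihedrals", "dihedral_k",
                            "dihedral_n", "dihedral_phi0"]}
    for frag in fragments:
        pieces["positions"].append(frag.positions)
        pieces["masses"].append(frag.masses)
        pieces["charges"].append(frag.charges)
        pieces["elements"].append(frag.elements)
        pieces["names"].append(frag.names)
        pieces["species"].append(frag.species)
        pieces["molecule_id"].append(frag.molecule_id + mol_offset)
        pieces["velocities"].append(frag.velocities)
        topo["bonds"].append(frag.bonds + offset)
        topo["bond_k"].append(frag.bond_k)
        topo["bond_r0"].append(frag.bond_r0)
        topo["angles"].append(frag.angles + offset)
        topo["angle_k"].append(frag.angle_k)
        topo["angle_theta0"].append(frag.angle_theta0)
        topo["dihedrals"].append(frag.dihedrals + offset)
        topo["dihedral_k"].append(frag.dihedral_k)
        topo["dihedral_n"].append(frag.dihedral_n)
        topo["dihedral_phi0"].append(frag.dihedral_phi0)
        offset += frag.n_atoms
        mol_offset += int(frag.molecule_id.max()) + 1 if frag.n_atoms else 0
    return ParticleSystem(
        positions=np.concatenate(pieces["positions"]),
        masses=np.concatenate(pieces["masses"]),
        charges=np.concatenate(pieces["charges"]),
        elements=np.concatenate(pieces["elements"]),
        names=np.concatenate(pieces["names"]),
        species=np.concatenate(pieces["species"]),
        molecule_id=np.concatenate(pieces["molecule_id"]),
        bonds=np.concatenate(topo["bonds"]).astype(int),
        bond_k=np.concatenate(topo["bond_k"]),
        bond_r0=np.concatenate(topo["bond_r0"]),
        angles=np.concatenate(topo["angles"]).astype(int),
        angle_k=np.concatenate(topo["angle_k"]),
        angle_theta0=np.concatenate(topo["angle_theta0"]),
        dihedrals=np.concatenate(topo["dihedrals"]).astype(int),
        dihedral_k=np.concatenate(topo["dihedral_k"]),
        dihedral_n=np.concatenate(topo["dihedral_n"]).astype(int),
        dihedral_phi0=np.concatenate(topo["dihedral_phi0"]),
        velocities=np.concatenate(pieces["velocities"]),
    )


def enumerate_angles_dihedrals(system: ParticleSystem,
                               angle_k: float = 60.0,
                               dihedral_k: float = 0.25,
                               dihedral_n: int = 3):
    """Fill angle and dihedral terms from the bond graph.

    The equilibrium angle is 120° when the center atom is a carbonyl-like
    carbon (bonded to a terminal O without hydrogens), 109.47° otherwise.
    """
    adj = system.bonded_adjacency()
    elements = system.elements
    angles, a_k, a_t0 = [], [], []
    for j in range(system.n_atoms):
        ns = sorted(adj[j])
        for a in range(len(ns)):
            for b in range(a + 1, len(ns)):
                angles.append((ns[a], j, ns[b]))
                a_k.append(angle_k)
                theta0 = 109.47
                if elements[j] == "C":
                    for nb in adj[j]:
                        if elements[nb] == "O" and len(adj[nb]) == 1:
                            theta0 = 120.0
                            break
                a_t0.append(np.deg2rad(theta0))
    dihedrals, d_k, d_n, d_p = [], [], [], []
    for j, k in system.bonds:
        j, k = int(j), int(k)
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l == j or l == i:
                    continue
                dihedrals.append((i, j, k, l))
                d_k.append(dihedral_k)
                d_n.append(dihedral_n)
                d_p.append(0.0)
    system.angles = np.array(angles, int).reshape(-1, 3)
    system.angle_k = np.array(a_k)
    system.angle_theta0 = np.array(a_t0)
    system.dihedrals = np.array(dihedrals, int).reshape(-1, 4)
    system.dihedral_k = np.array(d_k)
    system.dihedral_n = np.array(d_n, int)
    system.dihedral_phi0 = np.array(d_p)
    system.invalidate_topology_cache()
    return system
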