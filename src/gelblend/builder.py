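"""Construction of gelatin fibers, PVA chains and amorphous blend cells.

The gelatin model is three identical 15-residue fibers
(H₂N-Pro-Gly-Hyp-Hyp-Gly-Hyp-Pro-Gly-Glu-Gln-Gly-Pro-Ala-Gly-Lys-COOH);
PVA chains are linear runs of vinyl-alcohol units.  Amorphous cells are
grown unit-by-unit as a random walk with Monte Carlo selection of the
placement torsion (hard overlaps below 1 Å rejected), then relaxed by
energy minimization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import AMU_G
from .errors import ConfigurationError, PackingError
from .system import ParticleSystem, concatenate, enumerate_angles_dihedrals
from .templates import (K_BOND_H, K_BOND_HEAVY, MonomerTemplate, TemplateAtom,
                        VINYL_ALCOHOL, get_residue_template)

log = logging.getLogger(__name__)

GELATIN_SEQUENCE = ("Pro", "Gly", "Hyp", "Hyp", "Gly", "Hyp", "Pro", "Gly",
                    "Glu", "Gln", "Gly", "Pro", "Ala", "Gly", "Lys")

OVERLAP_THRESHOLD = 1.0   # Å, hard-overlap rejection during growth
_N_TRIALS = 25


# ---------------------------------------------------------------------------
# template capping

def _with_nterm_cap(tpl: MonomerTemplate) -> MonomerTemplate:
    atoms = [TemplateAtom(a.name, a.kind, a.charge, a.xyz.copy())
             for a in tpl.atoms]
    n_i = tpl.index("N")
    atoms[n_i] = TemplateAtom("N", "N", atoms[n_i].charge - 0.25,
                              atoms[n_i].xyz)
    h2 = atoms[n_i].xyz + 1.01 * np.array([-0.51, -0.76, 0.43]) / 1.0113
    atoms.append(TemplateAtom("H2", "H", 0.25, h2))
    bonds = list(tpl.internal_bonds) + [(n_i, len(atoms) - 1, 1.01)]
    return MonomerTemplate(name=tpl.name, atoms=atoms, internal_bonds=bonds,
                           head=tpl.head, tail=tpl.tail,
                           out_dir=tpl.out_dir, link_r0=tpl.link_r0)


def _with_cterm_cap(tpl: MonomerTemplate) -> MonomerTemplate:
    atoms = [TemplateAtom(a.name, a.kind, a.charge, a.xyz.copy())
             for a in tpl.atoms]
    c_i = tpl.index("C")
    atoms[c_i] = TemplateAtom("C", "C", atoms[c_i].charge + 0.10,
                              atoms[c_i].xyz)
    oxt = atoms[c_i].xyz + 1.34 * np.array([0.3, -0.8, -0.52]) / 1.0004
    hxt = oxt + 0.96 * np.array([0.6, -0.6, -0.53]) / 1.0020
    atoms.append(TemplateAtom("OXT", "O", -0.55, oxt))
    atoms.append(TemplateAtom("HXT", "H", 0.45, hxt))
    bonds = list(tpl.internal_bonds) + [(c_i, len(atoms) - 2, 1.34),
                                        (len(atoms) - 2, len(atoms) - 1, 0.96)]
    return MonomerTemplate(name=tpl.name, atoms=atoms, internal_bonds=bonds,
                           head=tpl.head, tail=tpl.tail,
                           out_dir=tpl.out_dir, link_r0=tpl.link_r0)


def gelatin_fiber_templates() -> list[MonomerTemplate]:
    """The capped 15-residue template sequence of one fiber."""
    tpls = [get_residue_template(r) for r in GELATIN_SEQUENCE]
    tpls[0] = _with_nterm_cap(tpls[0])
    tpls[-1] = _with_cterm_cap(tpls[-1])
    return tpls


def gelatin_fiber_mass() -> float:
    return float(sum(t.mass for t in gelatin_fiber_templates()))


def gelatin_molecule_mass() -> float:
    return 3.0 * gelatin_fiber_mass()


def pva_chain_mass(n_units: int) -> float:
    return float(n_units * VINYL_ALCOHOL.mass)


# ---------------------------------------------------------------------------
# chain growth

def _rotation_aligning_x(d: np.ndarray, spin: float) -> np.ndarray:
    """Rotation taking +x to unit vector d, followed by a spin about d."""
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(x, d)
    c = float(np.dot(x, d))
    if np.linalg.norm(v) < 1e-12:
        align = np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        align = np.eye(3) + vx + vx @ vx / (1.0 + c)
    ca, sa = np.cos(spin), np.sin(spin)
    k = d
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    spin_m = np.eye(3) * ca + sa * kx + (1 - ca) * np.outer(k, k)
    return spin_m @ align


def _min_image(dr: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return dr
    return dr - box * np.round(dr / box)


class _Packer:
    """Shared state for overlap-aware growth of several molecules."""

    def __init__(self, rng, box_lengths=None):
        self.rng = rng
        self.box = box_lengths
        self.coords: list[np.ndarray] = []
        self.heavy: list[bool] = []
        self._tree = None
        self._tree_size = 0

    def _rebuild_tree(self):
        pts = np.array([c for c, h in zip(self.coords, self.heavy) if h])
        if len(pts) == 0:
            self._tree = None
            return
        if self.box is not None:
            pts = np.mod(pts, self.box)
        self._tree = cKDTree(pts, boxsize=self.box)
        self._heavy_index = np.flatnonzero(self.heavy)
        self._tree_size = len(self.coords)

    def min_clearance(self, pts: np.ndarray, ignore: set) -> float:
        """Smallest distance from candidate heavy atoms to placed heavy
        atoms outside `ignore` (global indices)."""
        if self._tree is None or self._tree_size != len(self.coords):
            self._rebuild_tree()
        if self._tree is None:
            return np.inf
        q = np.mod(pts, self.box) if self.box is not None else pts
        dmin = np.inf
        # query a few nearest neighbours; enough to detect hard overlaps
        dists, idxs = self._tree.query(q, k=min(4, self._tree.n))
        dists = np.atleast_2d(dists)
        idxs = np.atleast_2d(idxs)
        for drow, irow in zip(dists, idxs):
            for d, i in zip(drow, irow):
                if not np.isfinite(d):
                    continue
                if int(self._heavy_index[i]) in ignore:
                    continue
                dmin = min(dmin, float(d))
                break
        return dmin

    def add(self, pts: np.ndarray, heavy_flags):
        for p, h in zip(pts, heavy_flags):
            self.coords.append(p)
            self.heavy.append(bool(h))


def _grow_chain(templates: list[MonomerTemplate], species: str,
                rng: np.random.Generator, packer: _Packer | None = None,
                start: np.ndarray | None = None) -> ParticleSystem:
    """Grow one chain from a template sequence; returns a fragment."""
    own = packer if packer is not None else _Packer(rng)
    if start is None:
        start = np.zeros(3)
    anchor = np.asarray(start, float)
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)

    pos, kinds, names, charges, masses, elements = [], [], [], [], [], []
    bonds, bond_r0 = [], []
    prev_tail_global = None
    prev_link_r0 = None
    prev_unit_ids: set = set()

    for tpl in templates:
        local = np.array([a.xyz for a in tpl.atoms])
        local = local - local[tpl.head]
        heavy = [a.element != "H" for a in tpl.atoms]
        base = len(own.coords)
        ignore = set(prev_unit_ids)

        best = None
        for _ in range(_N_TRIALS):
            spin = rng.uniform(0, 2 * np.pi)
            jitter = direction + 0.25 * rng.standard_normal(3)
            d = jitter / np.linalg.norm(jitter)
            R = _rotation_aligning_x(d, spin)
            cand = anchor + local @ R.T
            clearance = own.min_clearance(cand[np.array(heavy)], ignore)
            if best is None or clearance > best[0]:
                best = (clearance, cand, d, R)
            if clearance >= OVERLAP_THRESHOLD:
                break
        if best[0] < 0.35 * OVERLAP_THRESHOLD:
            raise PackingError(
                "could not place unit without severe overlap "
                f"(best clearance {best[0]:.2f} Å)")
        _, cand, d, R = best

        offset = len(pos)
        for a, p in zip(tpl.atoms, cand):
            pos.append(p)
            kinds.append(a.kind)
            names.append(a.name)
            charges.append(a.charge)
            masses.append(a.mass)
            elements.append(a.element)
        for i, j, r0 in tpl.internal_bonds:
            bonds.append((offset + i, offset + j))
            bond_r0.append(r0)
        if prev_tail_global is not None:
            bonds.append((prev_tail_global, offset + tpl.head))
            bond_r0.append(prev_link_r0)

        own.add(cand, heavy)
        prev_unit_ids = set(range(base, base + len(tpl.atoms)))
        prev_tail_global = offset + tpl.tail
        prev_link_r0 = tpl.link_r0
        out = R @ tpl.out_dir
        direction = out / np.linalg.norm(out)
        anchor = cand[tpl.tail] + tpl.link_r0 * direction

    bonds = np.array(bonds, int).reshape(-1, 2)
    bond_r0 = np.array(bond_r0)
    elements = np.array(elements)
    h_bond = np.array([(elements[i] == "H") or (elements[j] == "H")
                       for i, j in bonds])
    bond_k = np.where(h_bond, K_BOND_H, K_BOND_HEAVY)
    n = len(pos)
    return ParticleSystem(
        positions=np.array(pos), masses=np.array(masses),
        charges=np.array(charges), elements=elements,
        names=np.array(names), species=np.full(n, species),
        molecule_id=np.zeros(n, int),
        bonds=bonds, bond_k=bond_k, bond_r0=bond_r0,
    )


# ---------------------------------------------------------------------------
# public build operations

@dataclass
class GelatinFiber:
    sequence: tuple = GELATIN_SEQUENCE
    chain_id: int = 0
    fragment: ParticleSystem | None = None


@dataclass
class PVAChain:
    n_units: int = 20
    chain_id: int = 0
    fragment: ParticleSystem | None = None


def build_gelatin_model(rng=None) -> ParticleSystem:
    """Three identical-sequence 15-residue fibers with terminal caps.

    The fibers are grown independently (no inter-fiber bonds) and offset
    in space; atom count and total mass are deterministic.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(0 if rng is None else rng)
    tpls = gelatin_fiber_templates()
    frags = []
    for i in range(3):
        frag = _grow_chain(tpls, "gelatin", rng,
                           start=np.array([0.0, 12.0 * i, 0.0]))
        frags.append(frag)
    model = concatenate(frags)
    model.molecule_id[:] = 0   # one gelatin molecule = three fibers
    return model


def build_pva_chain(n_units: int, rng=None) -> ParticleSystem:
    """Linear PVA chain of ``n_units`` vinyl-alcohol units."""
    if n_units < 1:
        raise ValueError(f"n_units must be >= 1, got {n_units}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(0 if rng is None else rng)
    return _grow_chain([VINYL_ALCOHOL] * int(n_units), "pva", rng)


def mass_fraction_pva(system: ParticleSystem) -> float:
    """PVA mass / total mass of the system."""
    mask = system.species_mask("pva")
    total = system.total_mass
    if total == 0:
        return 0.0
    return float(system.masses[mask].sum() / total)


# ---------------------------------------------------------------------------
# composition and packing

@dataclass
class BlendComposition:
    """Molecule counts realizing a target PVA mass percentage."""

    n_gelatin_molecules: int
    n_pva_chains: int
    pva_units_per_chain: int = 20
    target_pva_mass_percent: float = 0.0
    tolerance: float = 2.5      # mass-% absolute

    def __post_init__(self):
        if self.n_gelatin_molecules < 0 or self.n_pva_chains < 0:
            raise ConfigurationError("molecule counts must be >= 0")
        if not 0.0 <= self.target_pva_mass_percent <= 100.0:
            raise ConfigurationError("target PVA percent must be in [0, 100]")
        if self.n_pva_chains > 0 and self.pva_units_per_chain < 1:
            raise ConfigurationError("pva_units_per_chain must be >= 1")
        dev = abs(self.achieved_pva_mass_percent
                  - self.target_pva_mass_percent)
        if dev > self.tolerance:
            raise ConfigurationError(
                f"achieved PVA mass percent "
                f"{self.achieved_pva_mass_percent:.2f} deviates from target "
                f"{self.target_pva_mass_percent:.2f} by more than "
                f"{self.tolerance} points")

    @property
    def total_mass(self) -> float:
        return (self.n_gelatin_molecules * gelatin_molecule_mass()
                + self.n_pva_chains * pva_chain_mass(self.pva_units_per_chain))

    @property
    def achieved_pva_mass_percent(self) -> float:
        total = self.total_mass
        if total == 0:
            return 0.0
        pva = self.n_pva_chains * pva_chain_mass(self.pva_units_per_chain)
        return 100.0 * pva / total

    @classmethod
    def from_target(cls, target_pva_mass_percent: float,
                    n_gelatin_molecules: int = 1,
                    pva_units_per_chain: int = 20,
                    tolerance: float = 2.5) -> "BlendComposition":
        gel_mass = n_gelatin_molecules * gelatin_molecule_mass()
        chain = pva_chain_mass(pva_units_per_chain)
        f = target_pva_mass_percent / 100.0
        if f >= 1.0:
            raise ConfigurationError(
                "100% PVA requires n_gelatin_molecules=0; construct directly")
        need = gel_mass * f / (1.0 - f)
        n_chains = int(round(need / chain))
        return cls(n_gelatin_molecules=n_gelatin_molecules,
                   n_pva_chains=n_chains,
                   pva_units_per_chain=pva_units_per_chain,
                   target_pva_mass_percent=target_pva_mass_percent,
                   tolerance=tolerance)


@dataclass
class SimulationCell:
    """Periodic amorphous cell plus its provenance."""

    system: ParticleSystem
    composition: BlendComposition
    seed: int
    initial_density: float
    max_force_after_min: float = np.nan
    stage_log: list = field(default_factory=list)

    @property
    def box_lengths(self) -> np.ndarray:
        return self.system.box_lengths

    def manifest(self) -> dict:
        return {
            "seed": int(self.seed),
            "n_gelatin_molecules": self.composition.n_gelatin_molecules,
            "n_pva_chains": self.composition.n_pva_chains,
            "pva_units_per_chain": self.composition.pva_units_per_chain,
            "target_pva_mass_percent":
                float(self.composition.target_pva_mass_percent),
            "achieved_pva_mass_percent":
                float(self.composition.achieved_pva_mass_percent),
            "pva_percent_convention": "mass",
            "initial_density_g_cm3": float(self.initial_density),
            "box_lengths_A": [float(x) for x in self.box_lengths],
            "n_atoms": self.system.n_atoms,
        }


def pack_amorphous_cell(composition: BlendComposition, seed: int,
                        initial_density: float = 0.5,
                        forcefield=None, force_tol: float = 1.0,
                        max_minimize_iter: int = 600,
                        max_retries: int = 3) -> SimulationCell:
    """Grow all chains into a periodic box and minimize.

    Growth is a random walk with Monte Carlo selection of each unit's
    placement torsion, rejecting hard overlaps (< 1 Å between non-bonded
    heavy atoms); the cell is then relaxed to a local energy minimum.
    Deterministic for a fixed seed.
    """
    from .engine import minimize
    from .forcefield import default_forcefield

    total_mass = composition.total_mass
    if total_mass <= 0:
        raise ConfigurationError("empty composition")
    volume = total_mass * AMU_G / initial_density * 1.0e24   # Å³
    box_l = volume ** (1.0 / 3.0)
    ff = forcefield if forcefield is not None else default_forcefield()
    if box_l < 2.0 * ff.cutoff:
        log.warning("box %.1f Å smaller than twice the cutoff; growing box "
                    "and lowering density", box_l)
        box_l = 2.0 * ff.cutoff * 1.02

    tpls = gelatin_fiber_templates()
    for attempt in range(max_retries):
        rng = np.random.default_rng([seed, attempt])
        packer = _Packer(rng, box_lengths=np.full(3, box_l))
        frags = []
        try:
            for _ in range(composition.n_gelatin_molecules):
                fibers = []
                for _ in range(3):
                    start = rng.uniform(0, box_l, 3)
                    fibers.append(_grow_chain(tpls, "gelatin", rng,
                                              packer=packer, start=start))
                gel = concatenate(fibers)
                gel.molecule_id[:] = 0
                frags.append(gel)
            for _ in range(composition.n_pva_chains):
                start = rng.uniform(0, box_l, 3)
                frags.append(_grow_chain(
                    [VINYL_ALCOHOL] * composition.pva_units_per_chain,
                    "pva", rng, packer=packer, start=start))
            break
        except PackingError:
            if attempt == max_retries - 1:
                raise PackingError(
                    "packing failed after retries",
                    achieved_density=initial_density)
    system = concatenate(frags)
    system.cell = np.diag(np.full(3, box_l))
    system.wrap()
    enumerate_angles_dihedrals(system)
    system.remove_net_charge()
    result = minimize(system, ff, force_tol=force_tol,
                      max_iter=max_minimize_iter, strict=False)
    cell = SimulationCell(system=result.system, composition=composition,
                          seed=seed, initial_density=initial_density,
                          max_force_after_min=result.max_force)
    log.info("packed cell: %d atoms, box %.2f Å, PVA %.1f mass%%",
             system.n_atoms, box_l, composition.achieved_pva_mass_percent)
    return cell
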