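"""Molecular observables of blend cells.

Energy density per trajectory frame, species-pair interaction
decomposition, fractional free volume (FFV), hydrogen-bond
donor/acceptor density and the grid-based pore-size distribution of the
model cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .constants import BONDI_RADII, COULOMB_K
from .engine import NeighborList, TrajectoryFrame, minimum_image
from .errors import DataError, GeometryError
from .forcefield import ForceField
from .system import ParticleSystem

_TERM_ALIASES = {"bonded": "bonded", "vdw": "vdw", "vdW": "vdw",
                 "electrostatic": "electrostatic", "total": "total"}


# ---------------------------------------------------------------------------
# energy density (per-frame energy over volume, averaged)

@dataclass
class EnergyDensityReport:
    term: str
    value: float            # kcal/(mol·Å³)
    n_frames: int


def energy_density(frames: list[TrajectoryFrame],
                   term: str = "total") -> EnergyDensityReport:
    """Mean of E_i/V_i over frames for the requested energy term."""
    if term not in _TERM_ALIASES:
        raise ValueError(f"unknown term {term!r}")
    term = _TERM_ALIASES[term]
    if len(frames) < 1:
        raise DataError("energy density needs at least one frame")
    ratios = []
    for fr in frames:
        if not np.isfinite(fr.volume) or fr.volume <= 0:
            raise DataError("frame with non-positive volume")
        e = fr.total if term == "total" else fr.energies[term]
        ratios.append(e / fr.volume)
    return EnergyDensityReport(term=term, value=float(np.mean(ratios)),
                               n_frames=len(frames))


# ---------------------------------------------------------------------------
# interaction decomposition

@dataclass
class InteractionDecomposition:
    gelatin_gelatin: float
    gelatin_pva: float
    pva_pva: float

    @property
    def total(self) -> float:
        return self.gelatin_gelatin + self.gelatin_pva + self.pva_pva


def pairwise_nonbonded(system: ParticleSystem, ff: ForceField,
                       nlist: NeighborList | None = None):
    """Per-pair nonbonded (LJ + Coulomb) energies; returns (pairs, e)."""
    if nlist is None:
        nlist = NeighborList(system, ff)
    else:
        nlist.ensure(system)
    pairs = nlist.pairs
    if len(pairs) == 0:
        return pairs, np.zeros(0)
    dr = minimum_image(system.positions[pairs[:, 0]]
                       - system.positions[pairs[:, 1]], system.cell)
    d2 = np.maximum(np.einsum("ij,ij->i", dr, dr), 1e-12)
    rc = ff.cutoff
    within = d2 <= rc * rc
    d = np.sqrt(d2)
    s6 = (nlist.sig_ij ** 2 / d2) ** 3
    sc6 = (nlist.sig_ij / rc) ** 6
    e = 4.0 * nlist.eps_ij * (s6 ** 2 - s6 - (sc6 ** 2 - sc6))
    if ff.coulomb:
        e = e + nlist.qq_ij / ff.dielectric * (1.0 / d - 1.0 / rc
                                               + (d - rc) / rc ** 2)
    return pairs, np.where(within, e, 0.0)


def interaction_energy(system: ParticleSystem, ff: ForceField,
                       groups: tuple = ("gelatin", "pva")
                       ) -> InteractionDecomposition:
    """Nonbonded energy split by species pair (same cutoff as the engine).

    For a cell without PVA the gelatin–PVA term is exactly zero.
    """
    for g in groups:
        if g not in ("gelatin", "pva"):
            raise ValueError(f"unknown group {g!r}")
    pairs, e = pairwise_nonbonded(system, ff)
    if len(pairs) == 0:
        return InteractionDecomposition(0.0, 0.0, 0.0)
    spec = system.species
    a_is_pva = spec[pairs[:, 0]] == "pva"
    b_is_pva = spec[pairs[:, 1]] == "pva"
    gg = float(e[~a_is_pva & ~b_is_pva].sum())
    pp = float(e[a_is_pva & b_is_pva].sum())
    gp = float(e[a_is_pva ^ b_is_pva].sum())
    return InteractionDecomposition(gelatin_gelatin=gg, gelatin_pva=gp,
                                    pva_pva=pp)


def interaction_energy_coulomb_pair(q1: float, q2: float, r: float,
                                    ff: ForceField) -> float:
    """Shifted-force Coulomb pair energy (helper mirroring the engine)."""
    if r > ff.cutoff:
        return 0.0
    return COULOMB_K * q1 * q2 / ff.dielectric * (
        1.0 / r - 1.0 / ff.cutoff + (r - ff.cutoff) / ff.cutoff ** 2)


# ---------------------------------------------------------------------------
# occupancy grid shared by FFV and pore analysis

def _occupancy_grid(system: ParticleSystem, probe_radius: float,
                    grid_spacing: float, min_points: int = 1):
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if system.cell is None:
        raise GeometryError("occupancy grid requires a periodic cell")
    cell = system.cell
    if not np.allclose(cell, np.diag(np.diag(cell))):
        raise GeometryError("occupancy grid requires an orthorhombic cell")
    box = np.diag(cell).astype(float)
    npts = np.maximum(np.round(box / grid_spacing).astype(int), 1)
    if np.any(npts < min_points):
        raise ValueError(
            f"grid too coarse: {npts} points per axis, need >= {min_points}")
    spacing = box / npts
    axes = [np.arange(n) * s + 0.5 * s for n, s in zip(npts, spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    occupied = np.zeros(len(grid), bool)
    if system.n_atoms:
        pos = np.mod(system.positions, box)
        radii = np.array([BONDI_RADII[e] for e in system.elements])
        for r in np.unique(radii):
            pts = pos[radii == r]
            tree = cKDTree(pts, boxsize=box)
            dist, _ = tree.query(grid)
            occupied |= dist <= (r + probe_radius)
    return occupied.reshape(tuple(npts)), spacing, box


# ---------------------------------------------------------------------------
# fractional free volume

@dataclass
class FFVResult:
    ffv: float
    probe_radius: float
    grid_spacing: float
    n_free_points: int
    n_total_points: int


def fractional_free_volume(system: ParticleSystem, probe_radius: float = 0.0,
                           grid_spacing: float = 0.5) -> FFVResult:
    """Fraction of grid points farther than r_vdW + probe from every atom.

    Probe radius 0 gives the geometric free volume; 1.3 Å approximates a
    water-sized probe.  Van der Waals radii are the Bondi set.
    """
    occ, spacing, _ = _occupancy_grid(system, probe_radius, grid_spacing)
    total = occ.size
    free = int(total - occ.sum())
    return FFVResult(ffv=free / total, probe_radius=probe_radius,
                     grid_spacing=float(np.max(spacing)),
                     n_free_points=free, n_total_points=total)


# ---------------------------------------------------------------------------
# hydrogen-bond donor/acceptor density

@dataclass
class DonorAcceptorDensity:
    n_donors: int
    n_acceptors: int
    n_hydroxyl: int
    volume: float           # Å³ (nan for fragments)

    @property
    def count(self) -> int:
        """Donors + acceptors; a hydroxyl O contributes one of each."""
        return self.n_donors + self.n_acceptors

    @property
    def per_nm3(self) -> float:
        return self.count / (self.volume * 1.0e-3)


def donor_acceptor_density(system: ParticleSystem) -> DonorAcceptorDensity:
    """Count hydrogen-bond donor and acceptor sites.

    Donors are O/N heavy atoms carrying at least one hydrogen; acceptors
    are all O and N atoms.  Each PVA unit's hydroxyl therefore counts
    once as donor and once as acceptor.
    """
    if system.n_atoms == 0:
        raise DataError("empty system")
    elements = system.elements
    known = np.isin(elements, list(BONDI_RADII))
    if not np.all(known):
        raise DataError("atoms with missing/unknown element labels")
    adj = system.bonded_adjacency()
    donors = 0
    acceptors = 0
    hydroxyl = 0
    for i, el in enumerate(elements):
        if el not in ("N", "O"):
            continue
        acceptors += 1
        h_neigh = sum(1 for j in adj[i] if elements[j] == "H")
        if h_neigh >= 1:
            donors += 1
        if el == "O" and h_neigh == 1 and \
                any(elements[j] == "C" for j in adj[i]):
            hydroxyl += 1
    vol = system.volume if system.cell is not None else float("nan")
    return DonorAcceptorDensity(n_donors=donors, n_acceptors=acceptors,
                                n_hydroxyl=hydroxyl, volume=vol)


# ---------------------------------------------------------------------------
# model pore distribution

@dataclass
class ModelPoreDistribution:
    diameters: np.ndarray           # Å, one per pore (connected free region)
    bin_edges: np.ndarray
    counts: np.ndarray
    probe_radius: float
    n_free_points: int = 0
    spanning: bool = field(default=False)


def _periodic_label(free: np.ndarray):
    """6-connected components of `free` with periodic wrap merging."""
    structure = ndimage.generate_binary_structure(3, 1)
    labels, n = ndimage.label(free, structure=structure)
    if n == 0:
        return labels, 0
    parent = list(range(n + 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for axis in range(3):
        lo = np.take(labels, 0, axis=axis)
        hi = np.take(labels, -1, axis=axis)
        both = (lo > 0) & (hi > 0)
        for a, b in zip(lo[both].ravel(), hi[both].ravel()):
            union(int(a), int(b))
    remap = np.array([0] + [find(i) for i in range(1, n + 1)])
    # compress to consecutive ids
    uniq = np.unique(remap[remap > 0])
    compress = np.zeros(n + 1, int)
    compress[uniq] = np.arange(1, len(uniq) + 1)
    labels = compress[remap[labels]]
    return labels, len(uniq)


def model_pore_distribution(system: ParticleSystem,
                            probe_radius: float = 0.0,
                            grid_spacing: float = 0.5,
                            bin_edges=None) -> ModelPoreDistribution:
    """Pore sizes of the model cell from the free-volume grid.

    Free grid points are grouped into periodically connected components
    (6-neighbor); each component's pore diameter is twice the maximum
    distance-to-occupied (periodic Euclidean distance transform) plus
    the probe diameter.  An atom-free cell yields a single pore spanning
    the box.
    """
    occ, spacing, box = _occupancy_grid(system, probe_radius, grid_spacing,
                                        min_points=3)
    free = ~occ
    n_free = int(free.sum())
    if bin_edges is None:
        bin_edges = np.linspace(0.0, float(np.max(box)), 11)
    bin_edges = np.asarray(bin_edges, float)

    if n_free == 0:
        return ModelPoreDistribution(
            diameters=np.zeros(0), bin_edges=bin_edges,
            counts=np.zeros(len(bin_edges) - 1, int),
            probe_radius=probe_radius, n_free_points=0)
    if occ.sum() == 0:
        d = float(np.max(box))
        counts, _ = np.histogram([d], bins=bin_edges)
        return ModelPoreDistribution(
            diameters=np.array([d]), bin_edges=bin_edges, counts=counts,
            probe_radius=probe_radius, n_free_points=n_free, spanning=True)

    labels, n_comp = _periodic_label(free)
    # periodic EDT: transform the 3x3x3 tiling, read the central block
    tiled = np.tile(free, (3, 3, 3))
    edt = ndimage.distance_transform_edt(tiled, sampling=spacing)
    nx, ny, nz = free.shape
    central = edt[nx:2 * nx, ny:2 * ny, nz:2 * nz]
    diameters = np.array([
        2.0 * float(central[labels == c].max()) + 2.0 * probe_radius
        for c in range(1, n_comp + 1)])
    counts, _ = np.histogram(diameters, bins=bin_edges)
    return ModelPoreDistribution(
        diameters=np.sort(diameters), bin_edges=bin_edges, counts=counts,
        probe_radius=probe_radius, n_free_points=n_free)
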