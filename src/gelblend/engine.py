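"""Periodic molecular-mechanics engine.

Energies, analytic forces and virial for harmonic bonds/angles, cosine
dihedrals, Lennard-Jones (potential-shifted) and shifted-force Coulomb
under the minimum-image convention; L-BFGS minimization; velocity-Verlet
dynamics with a Nosé–Hoover thermostat and an isotropic weak-coupling
barostat; the heat–anneal–equilibrate protocol used to relax amorphous
blend cells.

Internal units: Å, fs, amu, kcal/mol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree

from .constants import (AMU_G, COULOMB_K, KB, MVV_TO_KCALMOL, PA_TO_KCAL_A3)
from .errors import (DivergenceError, GeometryError, InstabilityError,
                     MinimizationError)
from .forcefield import ForceField
from .system import ParticleSystem

log = logging.getLogger(__name__)

ENERGY_TERMS = ("bonded", "vdw", "electrostatic")


# ---------------------------------------------------------------------------
# geometry helpers

def _cell_widths(cell: np.ndarray) -> np.ndarray:
    """Perpendicular widths of the cell (distance between opposite faces)."""
    vol = abs(np.linalg.det(cell))
    widths = []
    for i in range(3):
        a, b = cell[(i + 1) % 3], cell[(i + 2) % 3]
        widths.append(vol / np.linalg.norm(np.cross(a, b)))
    return np.array(widths)


def _check_geometry(system: ParticleSystem, ff: ForceField):
    if system.cell is None:
        return
    w = _cell_widths(system.cell)
    if np.min(w) < 2.0 * ff.cutoff:
        raise GeometryError(
            f"cell width {np.min(w):.2f} Å is below twice the cutoff "
            f"({2 * ff.cutoff:.2f} Å)")


def minimum_image(dr: np.ndarray, cell: np.ndarray | None) -> np.ndarray:
    if cell is None:
        return dr
    diag = np.diag(cell)
    if np.count_nonzero(cell - np.diag(diag)) == 0:
        return dr - diag * np.round(dr / diag)
    frac = dr @ np.linalg.inv(cell)
    frac -= np.round(frac)
    return frac @ cell


def _scatter_add(forces: np.ndarray, idx: np.ndarray, vec: np.ndarray):
    """forces[idx] += vec, fast for repeated indices (bincount-based)."""
    n = len(forces)
    for d in range(3):
        forces[:, d] += np.bincount(idx, weights=vec[:, d], minlength=n)


# ---------------------------------------------------------------------------
# neighbor list

class NeighborList:
    """Verlet pair list with a skin; 1-2 and 1-3 pairs are excluded."""

    def __init__(self, system: ParticleSystem, ff: ForceField,
                 skin: float = 2.0):
        self.skin = skin
        self.rlist = ff.cutoff + skin
        self._excl = self._encode_exclusions(system)
        self._eps, self._sig = ff.lj_tables(system.elements)
        self._charges = system.charges
        self.rebuild(system)

    @staticmethod
    def _encode_exclusions(system):
        n = system.n_atoms
        return np.array(sorted(i * n + j
                               for i, j in system.exclusion_pairs()))

    def rebuild(self, system: ParticleSystem):
        n = system.n_atoms
        pos = system.positions
        cell = system.cell
        diag = cell is not None and np.allclose(cell, np.diag(np.diag(cell)))
        if cell is None:
            tree = cKDTree(pos)
            pairs = tree.query_pairs(self.rlist, output_type="ndarray")
        elif diag:
            box = np.diag(cell)
            wrapped = np.mod(pos, box)
            tree = cKDTree(wrapped, boxsize=box)
            pairs = tree.query_pairs(self.rlist, output_type="ndarray")
        else:
            ii, jj = np.triu_indices(n, 1)
            dr = minimum_image(pos[ii] - pos[jj], cell)
            mask = np.einsum("ij,ij->i", dr, dr) <= self.rlist ** 2
            pairs = np.stack([ii[mask], jj[mask]], axis=1)
        if len(pairs):
            pairs = np.sort(pairs, axis=1)
            enc = pairs[:, 0] * n + pairs[:, 1]
            keep = ~np.isin(enc, self._excl)
            pairs = pairs[keep]
        self.pairs = pairs.astype(int).reshape(-1, 2)
        pi, pj = self.pairs[:, 0], self.pairs[:, 1]
        self.eps_ij = np.sqrt(self._eps[pi] * self._eps[pj])
        self.sig_ij = 0.5 * (self._sig[pi] + self._sig[pj])
        self.qq_ij = COULOMB_K * self._charges[pi] * self._charges[pj]
        self._pos_ref = pos.copy()

    def ensure(self, system: ParticleSystem):
        if system.positions.shape != self._pos_ref.shape:
            self.rebuild(system)
            return
        drift = np.abs(system.positions - self._pos_ref).max()
        if drift > 0.5 * self.skin:
            self.rebuild(system)


# ---------------------------------------------------------------------------
# energies, forces, virial

@dataclass
class EnergyForces:
    terms: dict
    forces: np.ndarray
    virial: np.ndarray          # W = Σ r⊗f over interactions, kcal/mol

    @property
    def total(self) -> float:
        return float(sum(self.terms.values()))

    @property
    def max_force(self) -> float:
        if len(self.forces) == 0:
            return 0.0
        return float(np.linalg.norm(self.forces, axis=1).max())


def compute_energy_forces(system: ParticleSystem, ff: ForceField,
                          nlist: NeighborList | None = None,
                          check_geometry: bool = True) -> EnergyForces:
    """Per-term energies, analytic forces and the position-space virial.

    Terms are ``bonded`` (bonds + angles + dihedrals), ``vdw`` and
    ``electrostatic``.  Forces are the exact negative gradient of the
    implemented energy.
    """
    if check_geometry:
        _check_geometry(system, ff)
    pos = system.positions
    cell = system.cell
    n = system.n_atoms
    forces = np.zeros((n, 3))
    W = np.zeros((3, 3))
    e_bonded = 0.0

    # bonds ------------------------------------------------------------
    if len(system.bonds):
        bi, bj = system.bonds[:, 0], system.bonds[:, 1]
        dr = minimum_image(pos[bi] - pos[bj], cell)
        d = np.linalg.norm(dr, axis=1)
        dev = d - system.bond_r0
        e_bonded += float(np.sum(0.5 * system.bond_k * dev ** 2))
        fmag = -system.bond_k * dev / np.maximum(d, 1e-12)
        fvec = fmag[:, None] * dr
        _scatter_add(forces, bi, fvec)
        _scatter_add(forces, bj, -fvec)
        W += np.einsum("ni,nj->ij", dr, fvec)

    # angles -----------------------------------------------------------
    if len(system.angles):
        ai, aj, ak = (system.angles[:, 0], system.angles[:, 1],
                      system.angles[:, 2])
        u = minimum_image(pos[ai] - pos[aj], cell)
        v = minimum_image(pos[ak] - pos[aj], cell)
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uhat = u / nu[:, None]
        vhat = v / nv[:, None]
        cos = np.clip(np.einsum("ij,ij->i", uhat, vhat), -1.0, 1.0)
        theta = np.arccos(cos)
        sin = np.maximum(np.sqrt(1.0 - cos ** 2), 1e-8)
        dev = theta - system.angle_theta0
        e_bonded += float(np.sum(0.5 * system.angle_k * dev ** 2))
        coef = -system.angle_k * dev
        fi = coef[:, None] * (cos[:, None] * uhat - vhat) / (nu * sin)[:, None]
        fk = coef[:, None] * (cos[:, None] * vhat - uhat) / (nv * sin)[:, None]
        _scatter_add(forces, ai, fi)
        _scatter_add(forces, ak, fk)
        _scatter_add(forces, aj, -(fi + fk))
        W += np.einsum("ni,nj->ij", u, fi) + np.einsum("ni,nj->ij", v, fk)

    # dihedrals ----------------------------------------------------------
    if len(system.dihedrals):
        di, dj, dk, dl = (system.dihedrals[:, 0], system.dihedrals[:, 1],
                          system.dihedrals[:, 2], system.dihedrals[:, 3])
        b1 = minimum_image(pos[dj] - pos[di], cell)
        b2 = minimum_image(pos[dk] - pos[dj], cell)
        b3 = minimum_image(pos[dl] - pos[dk], cell)
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        n1sq = np.maximum(np.einsum("ij,ij->i", n1, n1), 1e-12)
        n2sq = np.maximum(np.einsum("ij,ij->i", n2, n2), 1e-12)
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / np.maximum(nb2, 1e-12)
        phi = np.arctan2(y, x)
        karr = system.dihedral_k
        narr = system.dihedral_n
        p0 = system.dihedral_phi0
        e_bonded += float(np.sum(karr * (1.0 + np.cos(narr * phi - p0))))
        dedphi = -karr * narr * np.sin(narr * phi - p0)
        dphi_i = -(nb2 / n1sq)[:, None] * n1
        dphi_l = (nb2 / n2sq)[:, None] * n2
        t1 = (np.einsum("ij,ij->i", b1, b2) / nb2 ** 2)[:, None]
        t2 = (np.einsum("ij,ij->i", b3, b2) / nb2 ** 2)[:, None]
        dphi_j = -(1.0 + t1) * dphi_i + t2 * dphi_l
        dphi_k = t1 * dphi_i - (1.0 + t2) * dphi_l
        fi = -dedphi[:, None] * dphi_i
        fj = -dedphi[:, None] * dphi_j
        fk = -dedphi[:, None] * dphi_k
        fl = -dedphi[:, None] * dphi_l
        _scatter_add(forces, di, fi)
        _scatter_add(forces, dj, fj)
        _scatter_add(forces, dk, fk)
        _scatter_add(forces, dl, fl)
        # local positions relative to atom j (forces sum to zero)
        ri = -b1
        rk = b2
        rl = b2 + b3
        W += (np.einsum("ni,nj->ij", ri, fi)
              + np.einsum("ni,nj->ij", rk, fk)
              + np.einsum("ni,nj->ij", rl, fl))

    # nonbonded ----------------------------------------------------------
    if nlist is None:
        nlist = NeighborList(system, ff)
    else:
        nlist.ensure(system)
    e_vdw = 0.0
    e_coul = 0.0
    if len(nlist.pairs):
        pi, pj = nlist.pairs[:, 0], nlist.pairs[:, 1]
        dr = minimum_image(pos[pi] - pos[pj], cell)
        d2 = np.einsum("ij,ij->i", dr, dr)
        rc = ff.cutoff
        within = d2 <= rc * rc
        d2 = np.maximum(d2, 1e-12)
        d = np.sqrt(d2)

        sig, eps, qq = nlist.sig_ij, nlist.eps_ij, nlist.qq_ij
        s6 = (sig ** 2 / d2) ** 3
        s12 = s6 ** 2
        sc6 = (sig / rc) ** 6
        sc12 = sc6 ** 2
        e_lj = np.where(within, 4.0 * eps * (s12 - s6 - (sc12 - sc6)), 0.0)
        f_lj = np.where(within, 24.0 * eps * (2.0 * s12 - s6) / d2, 0.0)
        e_vdw = float(e_lj.sum())

        if ff.coulomb:
            inv_d = 1.0 / d
            e_c = np.where(within,
                           qq / ff.dielectric
                           * (inv_d - 1.0 / rc + (d - rc) / rc ** 2), 0.0)
            f_c = np.where(within,
                           qq / ff.dielectric
                           * (inv_d ** 2 - 1.0 / rc ** 2) / d, 0.0)
            e_coul = float(e_c.sum())
        else:
            f_c = 0.0

        fvec = (f_lj + f_c)[:, None] * dr
        _scatter_add(forces, pi, fvec)
        _scatter_add(forces, pj, -fvec)
        W += np.einsum("ni,nj->ij", dr, fvec)

    terms = {"bonded": e_bonded, "vdw": e_vdw, "electrostatic": e_coul}
    return EnergyForces(terms=terms, forces=forces, virial=W)


def stress_tensor(system: ParticleSystem, ff: ForceField,
                  nlist: NeighborList | None = None) -> np.ndarray:
    """Mechanical (tension-positive) stress tensor, kcal/(mol·Å³)."""
    if system.cell is None:
        raise GeometryError("stress requires a periodic cell")
    ef = compute_energy_forces(system, ff, nlist=nlist)
    kin = MVV_TO_KCALMOL * np.einsum(
        "n,ni,nj->ij", system.masses, system.velocities, system.velocities)
    return -(kin + ef.virial) / system.volume


def pressure(system: ParticleSystem, ff: ForceField,
             nlist: NeighborList | None = None) -> float:
    """Instantaneous pressure, kcal/(mol·Å³)."""
    return float(-np.trace(stress_tensor(system, ff, nlist)) / 3.0)


def density(system: ParticleSystem) -> float:
    """Mass density in g/cm³ (0 for an empty system)."""
    if system.n_atoms == 0:
        return 0.0
    return system.total_mass * AMU_G / (system.volume * 1.0e-24)


def kinetic_temperature(system: ParticleSystem) -> float:
    n = system.n_atoms
    if n == 0:
        return 0.0
    ke = 0.5 * MVV_TO_KCALMOL * float(
        np.sum(system.masses[:, None] * system.velocities ** 2))
    dof = max(3 * n - 3, 1)
    return 2.0 * ke / (dof * KB)


# ---------------------------------------------------------------------------
# minimization

@dataclass
class MinimizeResult:
    system: ParticleSystem
    energy: float
    max_force: float
    n_iterations: int
    converged: bool


def minimize(system: ParticleSystem, ff: ForceField,
             force_tol: float = 0.05, max_iter: int = 1000,
             nlist: NeighborList | None = None,
             strict: bool = False) -> MinimizeResult:
    """Relax to a local minimum with L-BFGS.

    ``strict=True`` raises :class:`MinimizationError` when the maximum
    atomic force stays above ``force_tol``; otherwise the achieved force
    is reported on the result.  Energy is non-increasing across accepted
    line-search steps.
    """
    work = system.copy()
    if nlist is None:
        nlist = NeighborList(work, ff)

    def objective(x):
        work.positions = x.reshape(-1, 3)
        nlist.ensure(work)
        ef = compute_energy_forces(work, ff, nlist=nlist,
                                   check_geometry=False)
        e = ef.total
        if not np.isfinite(e):
            raise DivergenceError("non-finite energy during minimization")
        return e, -ef.forces.ravel()

    _check_geometry(work, ff)
    x0 = work.positions.ravel().copy()
    total_iter = 0
    converged = False
    while total_iter < max_iter:
        res = optimize.minimize(
            objective, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter - total_iter,
                     "ftol": 1e-12, "gtol": 1e-10})
        total_iter += max(res.nit, 1)
        x0 = res.x
        work.positions = res.x.reshape(-1, 3)
        nlist.ensure(work)
        ef = compute_energy_forces(work, ff, nlist=nlist,
                                   check_geometry=False)
        if ef.max_force <= force_tol:
            converged = True
            break
        if res.nit == 0:
            break
    if strict and not converged:
        raise MinimizationError(
            f"max force {ef.max_force:.3g} above tolerance {force_tol:g} "
            f"after {total_iter} iterations")
    work.velocities = system.velocities.copy()
    return MinimizeResult(system=work, energy=ef.total,
                          max_force=ef.max_force,
                          n_iterations=total_iter, converged=converged)


# ---------------------------------------------------------------------------
# dynamics

@dataclass
class ThermoBaroState:
    """Thermostat/barostat targets and couplings."""

    temperature: float = 298.0      # K
    pressure_pa: float = 1.0        # Pa (as in the annealing protocol)
    timestep: float = 1.0           # fs
    tau_t: float = 50.0             # fs, Nosé–Hoover coupling time
    tau_p: float = 50.0             # fs, barostat coupling time
    compressibility: float = 3.1    # (kcal/mol/Å³)⁻¹, water-like
    xi: float = 0.0                 # thermostat friction variable
    max_scale_step: float = 0.005   # cap on per-step box rescale

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


@dataclass
class TrajectoryFrame:
    time: float                     # fs
    box_lengths: np.ndarray         # Å
    energies: dict                  # per-term potential, kcal/mol
    volume: float                   # Å³
    kinetic: float                  # kcal/mol
    temperature: float              # K
    positions: np.ndarray | None = None

    @property
    def total(self) -> float:
        return float(sum(self.energies.values()))


def initialize_velocities(system: ParticleSystem, temperature: float,
                          rng: np.random.Generator):
    if temperature <= 0 or system.n_atoms == 0:
        system.velocities = np.zeros((system.n_atoms, 3))
        return
    std = np.sqrt(KB * temperature / (system.masses * MVV_TO_KCALMOL))
    v = rng.standard_normal((system.n_atoms, 3)) * std[:, None]
    p = (system.masses[:, None] * v).sum(axis=0)
    v -= p / system.masses.sum()
    system.velocities = v
    t_now = kinetic_temperature(system)
    if t_now > 0:
        system.velocities *= np.sqrt(temperature / t_now)


def run_md(system: ParticleSystem, ff: ForceField, state: ThermoBaroState,
           ensemble: str = "NVT", n_steps: int = 1000, seed: int = 0,
           sample_every: int = 50, nlist: NeighborList | None = None,
           store_positions: bool = False, time_origin: float = 0.0,
           stage: str | None = None) -> list[TrajectoryFrame]:
    """Velocity-Verlet dynamics in the NVE, NVT or NPT ensemble.

    The system is advanced in place; sampled frames record per-term
    potential energies and the instantaneous volume.
    """
    ensemble = ensemble.upper()
    if ensemble not in ("NVE", "NVT", "NPT"):
        raise ValueError(f"unknown ensemble {ensemble!r}")
    if ensemble == "NPT" and system.cell is None:
        raise GeometryError("NPT requires a periodic cell")
    _check_geometry(system, ff)
    rng = np.random.default_rng(seed)
    if ensemble != "NVE" and not np.any(system.velocities):
        initialize_velocities(system, state.temperature, rng)

    dt = state.timestep
    masses = system.masses[:, None]
    inv_m = 1.0 / (masses * MVV_TO_KCALMOL)   # acceleration per force unit
    if nlist is None:
        nlist = NeighborList(system, ff)
    ef = compute_energy_forces(system, ff, nlist=nlist, check_geometry=False)
    p_target = state.pressure_pa * PA_TO_KCAL_A3
    frames: list[TrajectoryFrame] = []

    def record(step):
        ke = 0.5 * MVV_TO_KCALMOL * float(
            np.sum(system.masses[:, None] * system.velocities ** 2))
        frames.append(TrajectoryFrame(
            time=time_origin + step * dt,
            box_lengths=(system.box_lengths.copy()
                         if system.cell is not None else np.full(3, np.inf)),
            energies=dict(ef.terms),
            volume=system.volume if system.cell is not None else np.inf,
            kinetic=ke,
            temperature=kinetic_temperature(system),
            positions=system.positions.copy() if store_positions else None,
        ))

    record(0)
    for step in range(1, n_steps + 1):
        xi = state.xi if ensemble != "NVE" else 0.0
        v_half = (system.velocities
                  + 0.5 * dt * (ef.forces * inv_m - xi * system.velocities))
        system.positions = system.positions + dt * v_half
        nlist.ensure(system)
        ef = compute_energy_forces(system, ff, nlist=nlist,
                                   check_geometry=False)
        if ensemble == "NVE":
            system.velocities = v_half + 0.5 * dt * ef.forces * inv_m
        else:
            # Nosé–Hoover friction update from the half-step temperature
            system.velocities = v_half
            t_half = kinetic_temperature(system)
            state.xi = state.xi + dt * (t_half / max(state.temperature, 1e-12)
                                        - 1.0) / state.tau_t ** 2
            system.velocities = ((v_half + 0.5 * dt * ef.forces * inv_m)
                                 / (1.0 + 0.5 * dt * state.xi))
        t_now = kinetic_temperature(system)
        if t_now > 10.0 * max(state.temperature, 30.0):
            raise InstabilityError(
                f"temperature {t_now:.0f} K exploded at step {step}"
                + (f" of stage {stage}" if stage else ""),
                step=step, stage=stage)

        if ensemble == "NPT":
            kin = MVV_TO_KCALMOL * float(np.sum(
                system.masses[:, None] * system.velocities ** 2))
            p_inst = (kin + np.trace(ef.virial)) / (3.0 * system.volume)
            mu3 = 1.0 - (dt / state.tau_p) * state.compressibility \
                * (p_target - p_inst)
            mu = np.clip(np.cbrt(max(mu3, 1e-6)),
                         1.0 - state.max_scale_step,
                         1.0 + state.max_scale_step)
            system.cell = system.cell * mu
            system.positions = system.positions * mu
            if 2.0 * ff.cutoff > np.min(_cell_widths(system.cell)):
                raise GeometryError(
                    "cell shrank below twice the cutoff during NPT")
            nlist.ensure(system)

        if step % sample_every == 0 or step == n_steps:
            record(step)
    return frames


def equilibrate_protocol(system: ParticleSystem, ff: ForceField,
                         scale: float = 1.0, seed: int = 0,
                         timestep: float = 1.0, pressure_pa: float = 1.0,
                         sample_every: int = 50):
    """Heat to 600 K, hold, cool in 50 K steps to 298 K, then NPT and NVT
    equilibration holds.

    ``scale`` multiplies every stage duration; the stage sequence and
    temperature schedule are fixed:
    600 K NPT 300 ps; 550…300 K NPT 50 ps each; 298 K NPT 500 ps;
    298 K NVT 500 ps.  Returns ``(system, frames, stage_log)``.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must be in (0, 1]")
    stages = [("NPT", 600.0, 300.0)]
    stages += [("NPT", t, 50.0) for t in (550, 500, 450, 400, 350, 300)]
    stages += [("NPT", 298.0, 500.0), ("NVT", 298.0, 500.0)]

    state = ThermoBaroState(timestep=timestep, pressure_pa=pressure_pa)
    nlist = NeighborList(system, ff)
    rng = np.random.default_rng(seed)
    initialize_velocities(system, stages[0][1], rng)
    all_frames: list[TrajectoryFrame] = []
    stage_log = []
    t_origin = 0.0
    for idx, (ensemble, temp, dur_ps) in enumerate(stages):
        n_steps = max(1, int(round(dur_ps * 1000.0 * scale / timestep)))
        state.temperature = temp
        name = f"{idx}:{ensemble}@{temp:.0f}K"
        log.info("stage %s: %d steps", name, n_steps)
        try:
            frames = run_md(system, ff, state, ensemble=ensemble,
                            n_steps=n_steps, seed=seed + idx,
                            sample_every=sample_every, nlist=nlist,
                            time_origin=t_origin, stage=name)
        except InstabilityError as err:
            err.stage = name
            raise
        t_origin += n_steps * timestep
        all_frames.extend(frames if not all_frames else frames[1:])
        stage_log.append({"stage": idx, "ensemble": ensemble,
                          "temperature_K": temp,
                          "duration_ps": dur_ps * scale,
                          "n_steps": n_steps})
    return system, all_frames, stage_log
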