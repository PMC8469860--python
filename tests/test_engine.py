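"""Engine contracts: force-energy consistency, conservation laws,
minimization fixed points, thermostat/barostat behavior, densities."""

import numpy as np
import pytest

from gelblend.builder import build_pva_chain
from gelblend.constants import KCAL_A3_TO_GPA
from gelblend.engine import (ThermoBaroState, compute_energy_forces, density,
                             equilibrate_protocol, kinetic_temperature,
                             minimize, run_md)
from gelblend.errors import GeometryError, MinimizationError
from gelblend.forcefield import ForceField
from gelblend.system import enumerate_angles_dihedrals
from tests.conftest import make_atoms


def lj_dimer(r, eps=0.2, sigma=3.0, cell=None):
    s = make_atoms([[0, 0, 0], [r, 0, 0]], cell=cell)
    return s, ForceField(lj={"C": (eps, sigma)}, cutoff=9.0, coulomb=False)


class TestEnergyForces:
    def test_lj_minimum_energy_and_zero_force(self):
        eps, sigma = 0.2, 3.0
        s, ff = lj_dimer(2 ** (1 / 6) * sigma, eps, sigma, cell=[40, 40, 40])
        ef = compute_energy_forces(s, ff)
        # potential-shifted LJ: minimum sits at -eps minus the cutoff shift
        shift = 4 * eps * ((sigma / ff.cutoff) ** 12 - (sigma / ff.cutoff) ** 6)
        assert ef.terms["vdw"] == pytest.approx(-eps - shift, rel=1e-9)
        assert ef.max_force == pytest.approx(0.0, abs=1e-9)

    def test_harmonic_bond_at_rest_length_is_zero(self):
        s = make_atoms([[0, 0, 0], [1.0, 0, 0]], bonds=[[0, 1]],
                       bond_r0=1.0, cell=[20, 20, 20])
        ff = ForceField(lj={"C": (0.0, 0.5)}, cutoff=2.0, coulomb=False)
        ef = compute_energy_forces(s, ff)
        assert ef.terms["bonded"] == pytest.approx(0.0, abs=1e-12)

    def test_forces_match_central_differences(self, ff):
        # full chemistry: bonds, angles, dihedrals, LJ, Coulomb
        s = build_pva_chain(4, rng=7)
        enumerate_angles_dihedrals(s)
        s.cell = np.diag([30.0, 30.0, 30.0])
        ef = compute_energy_forces(s, ff)
        h = 1e-5
        rng = np.random.default_rng(0)
        worst = 0.0
        for i in rng.choice(s.n_atoms, 8, replace=False):
            for d in range(3):
                q = s.copy()
                q.positions[i, d] += h
                ep = compute_energy_forces(q, ff).total
                q = s.copy()
                q.positions[i, d] -= h
                em = compute_energy_forces(q, ff).total
                worst = max(worst, abs(-(ep - em) / (2 * h)
                                       - ef.forces[i, d]))
        assert worst < 1e-6 * ef.max_force

    def test_translation_invariance(self, ff):
        s = build_pva_chain(4, rng=7)
        enumerate_angles_dihedrals(s)
        s.cell = np.diag([30.0, 30.0, 30.0])
        e0 = compute_energy_forces(s, ff).terms
        q = s.copy()
        q.positions = q.positions + np.array([11.3, -7.9, 23.4])
        e1 = compute_energy_forces(q, ff).terms
        for k in e0:
            assert e1[k] == pytest.approx(e0[k], abs=1e-8)

    def test_box_smaller_than_twice_cutoff_rejected(self, ff):
        s = make_atoms([[0, 0, 0]], cell=[10, 10, 10])
        with pytest.raises(GeometryError):
            compute_energy_forces(s, ff)


class TestMinimize:
    def test_minimized_dimer_is_fixed_point(self):
        s, ff = lj_dimer(2 ** (1 / 6) * 3.0, cell=[40, 40, 40])
        res = minimize(s, ff, force_tol=1e-6)
        assert np.allclose(res.system.positions, s.positions, atol=1e-5)

    def test_stretched_bond_relaxes_to_rest_length(self):
        s = make_atoms([[0, 0, 0], [1.7, 0, 0]], bonds=[[0, 1]],
                       bond_r0=1.1, cell=[20, 20, 20])
        ff = ForceField(lj={"C": (0.0, 0.5)}, cutoff=2.0, coulomb=False)
        res = minimize(s, ff, force_tol=1e-8)
        d = np.linalg.norm(res.system.positions[1] - res.system.positions[0])
        assert d == pytest.approx(1.1, abs=1e-6)

    def test_bent_angle_relaxes_to_equilibrium(self):
        s = make_atoms([[1.0, 0, 0], [0, 0, 0], [0.3, 1.0, 0]],
                       bonds=[[0, 1], [1, 2]], bond_r0=1.0,
                       cell=[20, 20, 20])
        s.angles = np.array([[0, 1, 2]])
        s.angle_k = np.array([50.0])
        s.angle_theta0 = np.array([np.deg2rad(109.47)])
        ff = ForceField(lj={"C": (0.0, 0.5)}, cutoff=2.0, coulomb=False)
        res = minimize(s, ff, force_tol=1e-8)
        p = res.system.positions
        u, v = p[0] - p[1], p[2] - p[1]
        theta = np.degrees(np.arccos(
            np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v)))
        assert theta == pytest.approx(109.47, abs=1e-3)

    def test_strict_mode_raises_when_unconverged(self):
        rng = np.random.default_rng(0)
        s = make_atoms(rng.uniform(3, 17, (12, 3)), cell=[20, 20, 20])
        ff = ForceField(lj={"C": (0.3, 3.0)}, cutoff=9.0, coulomb=False)
        with pytest.raises(MinimizationError):
            minimize(s, ff, force_tol=1e-14, max_iter=1, strict=True)


class TestDynamics:
    def test_free_particle_moves_in_straight_line(self):
        s = make_atoms([[1.0, 1.0, 1.0]], cell=[30, 30, 30])
        s.velocities = np.array([[0.01, 0.0, 0.0]])
        ff = ForceField(lj={"C": (0.0, 0.5)}, cutoff=2.0, coulomb=False)
        state = ThermoBaroState(timestep=1.0)
        frames = run_md(s, ff, state, ensemble="NVE", n_steps=100,
                        sample_every=100, store_positions=True)
        assert np.allclose(frames[-1].positions[0], [2.0, 1.0, 1.0],
                           atol=1e-9)
        assert frames[-1].total == pytest.approx(frames[0].total, abs=1e-12)

    def test_nve_energy_drift_harmonic_dimer(self):
        # symplectic velocity Verlet: bounded drift at small timestep
        s = make_atoms([[0, 0, 0], [1.3, 0, 0]], bonds=[[0, 1]],
                       bond_r0=1.0, bond_k=50.0, cell=[20, 20, 20],
                       masses=[12.0, 12.0])
        ff = ForceField(lj={"C": (0.0, 0.5)}, cutoff=2.0, coulomb=False)
        state = ThermoBaroState(timestep=0.1)
        frames = run_md(s, ff, state, ensemble="NVE", n_steps=10_000,
                        sample_every=500)
        e = np.array([f.total + f.kinetic for f in frames])
        assert np.abs(e - e[0]).max() / abs(e[0]) < 1e-4

    def test_nve_momentum_conserved(self):
        s = make_atoms([[0, 0, 0], [1.3, 0.2, -0.1]], bonds=[[0, 1]],
                       bond_r0=1.0, bond_k=50.0, cell=[20, 20, 20],
                       masses=[12.0, 16.0])
        s.velocities = np.array([[0.002, -0.001, 0.0], [0.001, 0.003, 0.0]])
        p0 = (s.masses[:, None] * s.velocities).sum(axis=0)
        ff = ForceField(lj={"C": (0.0, 0.5)}, cutoff=2.0, coulomb=False)
        run_md(s, ff, ThermoBaroState(timestep=0.2), ensemble="NVE",
               n_steps=2000, sample_every=2000)
        p1 = (s.masses[:, None] * s.velocities).sum(axis=0)
        assert np.allclose(p0, p1, atol=1e-12)

    def test_nvt_holds_target_temperature(self):
        # toy LJ liquid at 300 K: long-run mean within 5% of target
        rng = np.random.default_rng(1)
        n = 27
        grid = np.array([[i, j, k] for i in range(3) for j in range(3)
                         for k in range(3)], float) * 5.0 + 2.0
        s = make_atoms(grid + rng.normal(0, 0.1, (n, 3)),
                       masses=np.full(n, 40.0), cell=[15, 15, 15])
        ff = ForceField(lj={"C": (0.2, 3.4)}, cutoff=7.0, coulomb=False)
        state = ThermoBaroState(temperature=300.0, timestep=2.0)
        frames = run_md(s, ff, state, ensemble="NVT", n_steps=4000,
                        seed=2, sample_every=10)
        temps = [f.temperature for f in frames[len(frames) // 2:]]
        assert 285.0 <= np.mean(temps) <= 315.0

    def test_npt_shrinks_toward_cohesion(self):
        # a cold sparse LJ solid under ~zero pressure contracts
        grid = np.array([[i, j, k] for i in range(3) for j in range(3)
                         for k in range(3)], float) * 6.0
        s = make_atoms(grid, masses=np.full(27, 40.0), cell=[18, 18, 18])
        ff = ForceField(lj={"C": (0.3, 3.4)}, cutoff=8.0, coulomb=False)
        state = ThermoBaroState(temperature=50.0, timestep=2.0,
                                pressure_pa=1.0)
        v0 = s.volume
        run_md(s, ff, state, ensemble="NPT", n_steps=2000, seed=3,
               sample_every=2000)
        assert s.volume < v0


class TestProtocol:
    def test_stage_schedule_and_final_ensemble(self):
        s = build_pva_chain(3, rng=0)
        enumerate_angles_dihedrals(s)
        s.cell = np.diag([16.0, 16.0, 16.0])
        s.wrap()
        ff = ForceField(lj={"C": (0.05, 3.2), "O": (0.05, 2.8),
                            "H": (0.01, 1.0)}, cutoff=6.0)
        _, _, log = equilibrate_protocol(s, ff, scale=1e-4, seed=0)
        temps = [st["temperature_K"] for st in log]
        assert temps == [600, 550, 500, 450, 400, 350, 300, 298, 298]
        assert [st["ensemble"] for st in log][-1] == "NVT"
        assert [st["ensemble"] for st in log][:-1] == ["NPT"] * 8

    def test_scale_multiplies_durations_only(self):
        s = build_pva_chain(3, rng=0)
        enumerate_angles_dihedrals(s)
        s.cell = np.diag([16.0, 16.0, 16.0])
        s.wrap()
        ff = ForceField(lj={"C": (0.05, 3.2), "O": (0.05, 2.8),
                            "H": (0.01, 1.0)}, cutoff=6.0)
        _, _, log1 = equilibrate_protocol(s.copy(), ff, scale=1e-4, seed=0)
        _, _, log2 = equilibrate_protocol(s.copy(), ff, scale=2e-4, seed=0)
        for a, b in zip(log1, log2):
            assert b["duration_ps"] == pytest.approx(2 * a["duration_ps"])
            assert b["temperature_K"] == a["temperature_K"]


class TestDensity:
    def test_known_mass_in_known_box(self):
        # 18 amu in a (10 Å)^3 box: 18·1.66054e-24 g / 1e-21 cm³
        s = make_atoms([[5, 5, 5]], masses=[18.0], cell=[10, 10, 10])
        assert density(s) == pytest.approx(0.0299, abs=2e-4)

    def test_doubling_box_divides_by_eight(self):
        s = make_atoms([[5, 5, 5]], masses=[18.0], cell=[10, 10, 10])
        d1 = density(s)
        s.cell = np.diag([20.0, 20.0, 20.0])
        assert density(s) == pytest.approx(d1 / 8)

    def test_empty_system_zero(self):
        s = make_atoms(np.zeros((0, 3)), elements=[], masses=[], charges=[],
                       cell=[10, 10, 10])
        assert density(s) == 0.0

    def test_kinetic_temperature_of_rest_is_zero(self):
        s = make_atoms([[0, 0, 0]], cell=[10, 10, 10])
        assert kinetic_temperature(s) == 0.0
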