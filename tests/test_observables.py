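"""Energy density, interaction decomposition, FFV, donor/acceptor
counting and grid-based pore analysis."""

import numpy as np
import pytest

from gelblend.builder import build_pva_chain
from gelblend.engine import NeighborList, TrajectoryFrame, \
    compute_energy_forces
from gelblend.errors import DataError
from gelblend.forcefield import ForceField
from gelblend.observables import (donor_acceptor_density, energy_density,
                                  fractional_free_volume, interaction_energy,
                                  model_pore_distribution)
from gelblend.system import concatenate, enumerate_angles_dihedrals
from tests.conftest import make_atoms


def frame(e_total, volume):
    return TrajectoryFrame(time=0.0, box_lengths=np.full(3, volume ** (1 / 3)),
                           energies={"bonded": e_total, "vdw": 0.0,
                                     "electrostatic": 0.0},
                           volume=volume, kinetic=0.0, temperature=0.0)


class TestEnergyDensity:
    def test_single_frame(self):
        rep = energy_density([frame(10.0, 2.0)], term="total")
        assert rep.value == pytest.approx(5.0)
        assert rep.n_frames == 1

    def test_two_frames_average_of_ratios(self):
        rep = energy_density([frame(10.0, 2.0), frame(6.0, 3.0)],
                             term="total")
        assert rep.value == pytest.approx(3.5)

    def test_duplicating_frames_leaves_value_unchanged(self):
        frames = [frame(10.0, 2.0), frame(6.0, 3.0)]
        assert energy_density(frames * 2, term="total").value == \
            pytest.approx(energy_density(frames, term="total").value)

    def test_zero_volume_frame_rejected(self):
        bad = frame(1.0, 2.0)
        bad.volume = 0.0
        with pytest.raises(DataError):
            energy_density([bad])

    def test_no_frames_rejected(self):
        with pytest.raises(DataError):
            energy_density([])


class TestInteractionDecomposition:
    def test_pure_gelatin_has_zero_cross_term(self, ff):
        s = make_atoms([[0, 0, 0], [4, 0, 0], [0, 4, 0]],
                       cell=[20, 20, 20], species="gelatin")
        dec = interaction_energy(s, ff)
        assert dec.gelatin_pva == 0.0

    def test_group_sums_equal_total_nonbonded(self, ff):
        # pairwise bookkeeping against the engine's total (dual route)
        gel = build_pva_chain(3, rng=1)
        gel.species[:] = "gelatin"
        pva = build_pva_chain(3, rng=2)
        pva.positions += np.array([6.0, 0.0, 0.0])
        s = concatenate([gel, pva])
        enumerate_angles_dihedrals(s)
        s.cell = np.diag([25.0, 25.0, 25.0])
        ff7 = ForceField(cutoff=7.0)
        dec = interaction_energy(s, ff7)
        ef = compute_energy_forces(s, ff7)
        total_nb = ef.terms["vdw"] + ef.terms["electrostatic"]
        assert dec.total == pytest.approx(total_nb, rel=1e-9)

    def test_isolated_pair_equals_pair_potential(self):
        a = make_atoms([[0, 0, 0]], species="gelatin")
        b = make_atoms([[4.0, 0, 0]], species="pva")
        s = concatenate([a, b])
        s.cell = np.diag([20.0, 20.0, 20.0])
        ff = ForceField(lj={"C": (0.2, 3.0)}, cutoff=9.0, coulomb=False)
        dec = interaction_energy(s, ff)
        sig6 = (3.0 / 4.0) ** 6
        shift = 4 * 0.2 * ((3.0 / 9.0) ** 12 - (3.0 / 9.0) ** 6)
        assert dec.gelatin_pva == pytest.approx(
            4 * 0.2 * (sig6 ** 2 - sig6) - shift, rel=1e-12)

    def test_unknown_group_rejected(self, ff):
        s = make_atoms([[0, 0, 0]], cell=[20, 20, 20])
        with pytest.raises(ValueError):
            interaction_energy(s, ff, groups=("gelatin", "starch"))


class TestFFV:
    def test_empty_box_is_all_free(self):
        s = make_atoms(np.zeros((0, 3)), elements=[], masses=[], charges=[],
                       cell=[10, 10, 10])
        assert fractional_free_volume(s).ffv == 1.0

    def test_fully_occupied_box(self):
        # one atom whose radius covers the whole cell
        s = make_atoms([[5, 5, 5]], cell=[4, 4, 4])
        res = fractional_free_volume(s, probe_radius=10.0, grid_spacing=0.5)
        assert res.ffv == 0.0

    def test_single_atom_matches_sphere_volume(self):
        # FFV -> 1 - (4/3)πr³/V as the grid refines (Bondi C: 1.70 Å)
        L = 10.0
        s = make_atoms([[5, 5, 5]], cell=[L, L, L])
        r = 1.70
        expected = 1.0 - (4.0 / 3.0) * np.pi * r ** 3 / L ** 3
        res = fractional_free_volume(s, probe_radius=0.0, grid_spacing=0.2)
        assert res.ffv == pytest.approx(expected, abs=0.005)

    def test_grid_convergence_better_than_one_percent(self):
        s = build_pva_chain(5, rng=3)
        s.cell = np.diag([14.0, 14.0, 14.0])
        s.wrap()
        a = fractional_free_volume(s, grid_spacing=0.5).ffv
        b = fractional_free_volume(s, grid_spacing=0.25).ffv
        assert abs(a - b) < 0.01

    def test_bad_spacing_rejected(self):
        s = make_atoms([[0, 0, 0]], cell=[10, 10, 10])
        with pytest.raises(ValueError):
            fractional_free_volume(s, grid_spacing=0.0)


class TestDonorAcceptor:
    def test_pva_chain_site_counts(self):
        chain = build_pva_chain(10)
        da = donor_acceptor_density(chain)
        assert da.n_hydroxyl == 10
        assert da.n_donors == 10
        assert da.n_acceptors == 10
        assert da.count == 20

    def test_doubling_volume_halves_density(self):
        chain = build_pva_chain(4)
        chain.cell = np.diag([20.0, 20.0, 20.0])
        d1 = donor_acceptor_density(chain).per_nm3
        chain.cell = np.diag([20.0 * 2 ** (1 / 3)] * 3)
        d2 = donor_acceptor_density(chain).per_nm3
        assert d2 == pytest.approx(d1 / 2)

    def test_adding_pva_strictly_increases_count(self):
        from gelblend.builder import build_gelatin_model
        gel = build_gelatin_model(rng=0)
        base = donor_acceptor_density(gel).count
        both = concatenate([gel, build_pva_chain(10, rng=1)])
        assert donor_acceptor_density(both).count == base + 20


class TestModelPores:
    def test_empty_box_single_spanning_pore(self):
        s = make_atoms(np.zeros((0, 3)), elements=[], masses=[], charges=[],
                       cell=[10, 10, 10])
        dist = model_pore_distribution(s, grid_spacing=1.0)
        assert len(dist.diameters) == 1
        assert dist.spanning
        assert dist.diameters[0] == pytest.approx(10.0)

    def test_two_separated_voids_from_planned_layout(self):
        # two slabs of atoms at x ~ 2.5 and x ~ 7.5 partition the box
        # into two periodic void slabs -> exactly two pore components
        pts = []
        for y in np.arange(0.5, 10.0, 1.0):
            for z in np.arange(0.5, 10.0, 1.0):
                pts.append([2.5, y, z])
                pts.append([7.5, y, z])
        s = make_atoms(pts, cell=[10, 10, 10])
        dist = model_pore_distribution(s, grid_spacing=0.5)
        assert len(dist.diameters) == 2

    def test_probe_growth_never_frees_points(self):
        s = build_pva_chain(5, rng=3)
        s.cell = np.diag([14.0, 14.0, 14.0])
        s.wrap()
        n0 = model_pore_distribution(s, probe_radius=0.0,
                                     grid_spacing=0.7).n_free_points
        n1 = model_pore_distribution(s, probe_radius=1.0,
                                     grid_spacing=0.7).n_free_points
        assert n1 <= n0

    def test_counts_sum_to_pore_count(self):
        s = build_pva_chain(5, rng=3)
        s.cell = np.diag([14.0, 14.0, 14.0])
        s.wrap()
        dist = model_pore_distribution(s, grid_spacing=0.7)
        assert dist.counts.sum() == len(dist.diameters)

    def test_too_coarse_grid_rejected(self):
        s = make_atoms([[0, 0, 0]], cell=[10, 10, 10])
        with pytest.raises(ValueError):
            model_pore_distribution(s, grid_spacing=6.0)
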