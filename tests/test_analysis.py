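"""Contact maps, SASA, pore profiles, water counts, salt bridges, RMSD series."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from transit.analysis import (LumenSpec, SaltBridgeSpec, contact_set,
                              count_lumen_waters, differential_contacts,
                              pore_profile, rmsd_series, sasa,
                              salt_bridge_distances)
from transit.errors import AnalysisError
from transit.structio import Atom, Selection, Structure, Trajectory, select
from transit.synthetic import (BundleSpec, HingeSpec, make_bundle,
                               make_cylinder_fixture, make_state_pair,
                               default_lumen_spec, place_waters)


def brute_force_contacts(structure, cutoff=3.5, min_separation=3):
    """O(n²) all-pairs oracle for the contact map."""
    atoms = [(i, a) for i, a in enumerate(structure.atoms)
             if a.is_heavy and not a.is_water]
    coords = structure.coords
    pairs = set()
    for x, (i, a) in enumerate(atoms):
        for j, b in atoms[x + 1:]:
            ka, kb = (a.chain, a.resid), (b.chain, b.resid)
            if ka == kb:
                continue
            if ka[0] == kb[0] and abs(ka[1] - kb[1]) <= min_separation:
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                pairs.add((min(ka, kb), max(ka, kb)))
    return pairs


class TestContacts:
    def two_residue_structure(self, factory, distance):
        return factory([[0, 0, 0], [distance, 0, 0]], names=["CB", "CB"],
                       resids=[1, 10])

    def test_inclusive_cutoff_boundary(self, toy_structure_factory):
        inside = self.two_residue_structure(toy_structure_factory, 3.4)
        outside = self.two_residue_structure(toy_structure_factory, 3.6)
        assert len(contact_set(inside)) == 1
        assert len(contact_set(outside)) == 0
        boundary = self.two_residue_structure(toy_structure_factory, 3.5)
        assert len(contact_set(boundary)) == 1  # "within" read inclusively

    def test_sequence_neighbours_excluded(self, toy_structure_factory):
        s = toy_structure_factory([[0, 0, 0], [3.0, 0, 0]], resids=[5, 8])
        assert len(contact_set(s)) == 0
        s2 = toy_structure_factory([[0, 0, 0], [3.0, 0, 0]], resids=[5, 9])
        assert len(contact_set(s2)) == 1

    def test_interchain_pairs_always_eligible(self, toy_structure_factory):
        from tests.conftest import make_toy_structure
        a = Atom(1, "CB", "C", 5, "ALA", "A", np.array([0.0, 0, 0]))
        b = Atom(2, "CB", "C", 6, "ALA", "B", np.array([3.0, 0, 0]))
        s = Structure([a, b])
        assert len(contact_set(s)) == 1

    def test_hydrogens_and_waters_ignored(self, toy_structure_factory):
        s = toy_structure_factory([[0, 0, 0], [3.0, 0, 0]],
                                  names=["CB", "H"], resids=[1, 10],
                                  elements=["C", "H"])
        assert len(contact_set(s)) == 0

    def test_matches_brute_force_on_bundle(self, small_bundle, standard_bundle):
        for fixture in (small_bundle, standard_bundle):
            ours = contact_set(fixture).pairs
            oracle = brute_force_contacts(fixture)
            assert ours == oracle


class TestDifferentialContacts:
    def test_identical_structures_empty(self, small_bundle):
        diff = differential_contacts(small_bundle, small_bundle)
        assert not diff.broken and not diff.formed

    def test_translated_helix_breaks_its_contacts(self, small_bundle):
        moved = small_bundle.copy()
        chain, resids = small_bundle.annotation.residues_of("TM1")
        resid_set = set(resids)
        for a in moved.atoms:
            if a.resid in resid_set:
                a.coords = a.coords + np.array([30.0, 0.0, 0.0])
        diff = differential_contacts(small_bundle, moved)
        assert diff.broken
        for p, q in diff.broken:
            assert p[1] in resid_set or q[1] in resid_set
        for p, q in diff.formed:
            # any formed contacts must involve the moved helix too
            assert p[1] in resid_set or q[1] in resid_set

    def test_swap_antisymmetry(self, state_pair):
        of, ifs = state_pair
        fwd = differential_contacts(of, ifs)
        rev = differential_contacts(ifs, of)
        assert fwd.broken == rev.formed
        assert fwd.formed == rev.broken

    def test_roster_mismatch_rejected(self, small_bundle, toy_structure_factory):
        other = toy_structure_factory([[0, 0, 0]])
        with pytest.raises(AnalysisError):
            differential_contacts(small_bundle, other)


class TestSasa:
    def test_isolated_sphere_analytic(self, toy_structure_factory):
        s = toy_structure_factory([[0, 0, 0]], names=["C"])
        s.atoms[0].vdw_radius = 1.7
        area = sasa(s, Selection(np.array([0])), probe=1.4)
        analytic = 4 * np.pi * (1.7 + 1.4) ** 2
        assert area == pytest.approx(analytic, rel=0.01)

    def test_two_coincident_atoms_count_once(self, toy_structure_factory):
        s = toy_structure_factory([[0, 0, 0], [0, 0, 0]], names=["C", "C"],
                                  resids=[1, 2])
        total = sasa(s, Selection(np.array([0, 1])))
        one = 4 * np.pi * (1.7 + 1.4) ** 2
        assert total == pytest.approx(one, rel=0.02)

    def test_fully_buried_atom_is_zero(self):
        # Central atom caged by a dense shell of atoms.
        shell = []
        golden = np.pi * (1 + 5 ** 0.5)
        for i in range(60):
            phi = np.arccos(1 - 2 * (i + 0.5) / 60)
            theta = golden * i
            shell.append([3.0 * np.sin(phi) * np.cos(theta),
                          3.0 * np.sin(phi) * np.sin(theta),
                          3.0 * np.cos(phi)])
        atoms = [Atom(1, "C", "C", 1, "ALA", "A", np.zeros(3))]
        atoms += [Atom(i + 2, "C", "C", i + 2, "ALA", "A", np.array(p))
                  for i, p in enumerate(shell)]
        s = Structure(atoms)
        assert sasa(s, Selection(np.array([0]))) == 0.0

    def test_point_density_convergence(self, small_bundle):
        sel = select(small_bundle, "resid 1..6")
        a = sasa(small_bundle, sel, n_points=960)
        b = sasa(small_bundle, sel, n_points=1920)
        assert abs(a - b) / b < 0.005

    def test_empty_selection_warns_and_returns_zero(self, small_bundle):
        with pytest.warns(UserWarning):
            assert sasa(small_bundle, Selection(np.array([], dtype=int))) == 0.0


class TestPoreProfile:
    def test_cylinder_matches_analytic_radius(self):
        cage = make_cylinder_fixture(8.0, n_rings=24, atoms_per_ring=36,
                                     vdw=1.7)
        prof = pore_profile(cage, z_range=(-8, 8), dz=0.5, optimizer_seed=0)
        assert np.all(np.isfinite(prof.radius))
        np.testing.assert_allclose(prof.radius, 8.0 - 1.7, atol=0.1)

    def test_constriction_detected(self):
        radii = [8.0] * 10 + [4.0] + [8.0] * 10
        cage = make_cylinder_fixture(radii, atoms_per_ring=36, vdw=1.7)
        prof = pore_profile(cage, z_range=(-10, 10), dz=0.5, optimizer_seed=0)
        assert prof.radius.min() == pytest.approx(4.0 - 1.7, abs=0.1)
        mid = np.argmin(np.abs(prof.z))
        assert prof.radius[mid] < 3.5

    def test_radius_nonnegative(self, small_bundle):
        prof = pore_profile(small_bundle, z_range=(-9, 9), dz=1.0,
                            optimizer_seed=1)
        finite = prof.radius[np.isfinite(prof.radius)]
        assert np.all(finite >= 0.0)

    def test_matches_dense_grid_search(self):
        radii = [6.0] * 4 + [4.5] * 3 + [6.0] * 4
        cage = make_cylinder_fixture(radii, atoms_per_ring=24, vdw=1.7)
        coords = cage.coords
        vdw = np.array([a.vdw_radius for a in cage.atoms])
        prof = pore_profile(cage, z_range=(-3, 3), dz=1.0, optimizer_seed=3)
        xs = np.arange(-3.0, 3.0001, 0.1)
        for z, r in zip(prof.z, prof.radius):
            grid = np.array([[x, y, z] for x in xs for y in xs])
            d = np.linalg.norm(coords[None, :, :] - grid[:, None, :], axis=2)
            best = np.max(np.min(d - vdw[None, :], axis=1))
            assert r == pytest.approx(max(best, 0.0), abs=0.15)


class TestLumenWaters:
    def lumen_with_anchor(self, factory):
        # Single anchor atom at the origin plane; EC window 2..15.
        s = factory([[0, 0, 5.0]], names=["CA"])
        return s, LumenSpec(ec_anchors=Selection(np.array([0])),
                            ic_anchors=Selection(np.array([0])))

    def add_water(self, s, xyz):
        out = s.copy()
        out.atoms.append(Atom(len(s.atoms) + 1, "O", "O", 999, "HOH", "W",
                              np.array(xyz, dtype=float), is_water=True))
        return out

    def test_water_in_window_near_anchor_counted(self, toy_structure_factory):
        s, lum = self.lumen_with_anchor(toy_structure_factory)
        s = self.add_water(s, [3.0, 0.0, 9.0])  # z in (2,15), 5 Å from anchor
        waters = select(s, "water")
        assert count_lumen_waters(s, waters, lum, "EC") == 1

    def test_water_far_from_anchors_not_counted(self, toy_structure_factory):
        s, lum = self.lumen_with_anchor(toy_structure_factory)
        s = self.add_water(s, [12.0, 0.0, 10.0])  # 12.6 Å from anchor
        waters = select(s, "water")
        assert count_lumen_waters(s, waters, lum, "EC") == 0

    def test_water_outside_window_not_counted(self, toy_structure_factory):
        s, lum = self.lumen_with_anchor(toy_structure_factory)
        s = self.add_water(s, [3.0, 0.0, 1.0])  # near anchor but z < 2
        waters = select(s, "water")
        assert count_lumen_waters(s, waters, lum, "EC") == 0

    def test_empty_anchors_is_an_error(self, toy_structure_factory):
        s, lum = self.lumen_with_anchor(toy_structure_factory)
        s = self.add_water(s, [3.0, 0.0, 9.0])
        lum.ec_anchors = Selection(np.array([], dtype=int))
        with pytest.raises(AnalysisError, match="anchor"):
            count_lumen_waters(s, select(s, "water"), lum, "EC")

    def test_planted_waters_all_recovered(self, standard_bundle):
        lum = default_lumen_spec(standard_bundle)
        wet = place_waters(standard_bundle, lum, "EC", 25, seed=4)
        waters = select(wet, "water")
        lum_wet = default_lumen_spec(wet)
        assert count_lumen_waters(wet, waters, lum_wet, "EC") == 25
        assert count_lumen_waters(wet, waters, lum_wet, "IC") == 0


def arg_asp_fixture(d_nh_od=2.8):
    """An arginine/aspartate pair with a known minimum N–O distance."""
    atoms = [
        Atom(1, "CA", "C", 1, "ARG", "A", np.array([0.0, 0, 0])),
        Atom(2, "NE", "N", 1, "ARG", "A", np.array([1.0, 0, 0])),
        Atom(3, "NH1", "N", 1, "ARG", "A", np.array([2.0, 0, 0])),
        Atom(4, "NH2", "N", 1, "ARG", "A", np.array([2.0, 1.0, 0])),
        Atom(5, "CA", "C", 9, "ASP", "A", np.array([6.0, 0, 0])),
        Atom(6, "OD1", "O", 9, "ASP", "A", np.array([2.0 + d_nh_od, 0, 0])),
        Atom(7, "OD2", "O", 9, "ASP", "A", np.array([6.0, 1.0, 0])),
    ]
    return Structure(atoms)


class TestSaltBridges:
    def make_traj(self, s, n_frames=3):
        frames = np.stack([s.coords + 0.5 * i for i in range(n_frames)])
        return Trajectory(frames, np.arange(1.0, n_frames + 1), template=s)

    def test_constructed_distance(self):
        s = arg_asp_fixture(2.8)
        traj = self.make_traj(s, n_frames=1)
        spec = SaltBridgeSpec(acidic=("A", 9), basic=("A", 1))
        d = salt_bridge_distances(traj, spec)
        assert d[0] == pytest.approx(2.8)

    def test_symmetric_under_oxygen_swap(self):
        s = arg_asp_fixture(2.8)
        swapped = arg_asp_fixture(2.8)
        c6 = swapped.atoms[5].coords.copy()
        swapped.atoms[5].coords = swapped.atoms[6].coords.copy()
        swapped.atoms[6].coords = c6
        spec = SaltBridgeSpec(acidic=("A", 9), basic=("A", 1))
        d1 = salt_bridge_distances(self.make_traj(s, 1), spec)
        d2 = salt_bridge_distances(self.make_traj(swapped, 1), spec)
        assert d1[0] == pytest.approx(d2[0])

    def test_matches_brute_force_all_pairs(self, rng):
        s = arg_asp_fixture()
        for a in s.atoms:
            a.coords = a.coords + rng.normal(scale=0.5, size=3)
        traj = self.make_traj(s, n_frames=4)
        spec = SaltBridgeSpec(acidic=("A", 9), basic=("A", 1))
        d = salt_bridge_distances(traj, spec)
        o_idx = [5, 6]
        n_idx = [1, 2, 3]
        for f in range(4):
            brute = min(np.linalg.norm(traj.frames[f][i] - traj.frames[f][j])
                        for i in o_idx for j in n_idx)
            assert d[f] == pytest.approx(brute)

    def test_missing_sidechain_atoms_error_names_residue(self):
        s = arg_asp_fixture()
        s.atoms = [a for a in s.atoms if a.name not in ("OD1", "OD2")]
        traj = self.make_traj(s, 1)
        spec = SaltBridgeSpec(acidic=("A", 9), basic=("A", 1))
        with pytest.raises(AnalysisError, match="A:9"):
            salt_bridge_distances(traj, spec)


class TestRmsdSeries:
    def test_copies_of_reference_give_zeros(self, small_bundle):
        frames = np.stack([small_bundle.coords] * 4)
        traj = Trajectory(frames, np.arange(1.0, 5.0), template=small_bundle)
        sel = select(small_bundle, "name CA")
        np.testing.assert_allclose(rmsd_series(traj, small_bundle, sel), 0.0,
                                   atol=1e-12)

    def test_invariant_under_global_rigid_motion(self, small_bundle, rng):
        frames = np.stack([small_bundle.coords + rng.normal(scale=0.2,
                                                            size=(small_bundle.n_atoms, 3))
                           for _ in range(3)])
        traj = Trajectory(frames, np.arange(1.0, 4.0), template=small_bundle)
        sel = select(small_bundle, "name CA")
        base = rmsd_series(traj, small_bundle, sel)
        rot = Rotation.from_rotvec([0.3, -0.2, 1.1])
        moved = Trajectory(np.stack([rot.apply(f) + 5.0 for f in frames]),
                           np.arange(1.0, 4.0), template=small_bundle)
        np.testing.assert_allclose(rmsd_series(moved, small_bundle, sel), base,
                                   atol=1e-8)
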