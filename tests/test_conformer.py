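"""Dihedrals, Ramachandran free energies, H-bond classes, RMSD and RoG."""

import numpy as np
import pytest

from peptaibiome.conformer import (Ensemble, R_KCAL, backbone_dihedrals,
                                   classify_region, detect_hbonds, fes_2d,
                                   mirror, radius_of_gyration,
                                   rama_free_energy, read_pdb_ensemble,
                                   rmsd_to_average, rog_series,
                                   write_pdb_ensemble)
from peptaibiome.errors import (InsufficientEnsembleError, TopologyError)
from peptaibiome.simulate import HelixSimConfig, generate_helix_ensemble


@pytest.fixture(scope="module")
def alpha_right():
    return generate_helix_ensemble(HelixSimConfig(
        n_residues=10, helix_type="alpha", handedness="right", n_frames=3))


@pytest.fixture(scope="module")
def three10_left():
    return generate_helix_ensemble(HelixSimConfig(
        n_residues=10, helix_type="three10", handedness="left", n_frames=3))


class TestDihedrals:
    def test_ideal_right_alpha_helix_angles(self, alpha_right):
        dih = backbone_dihedrals(alpha_right)
        assert np.nanmean(dih.phi) == pytest.approx(-57.0, abs=0.5)
        assert np.nanmean(dih.psi) == pytest.approx(-47.0, abs=0.5)

    def test_termini_undefined(self, alpha_right):
        dih = backbone_dihedrals(alpha_right)
        assert np.all(np.isnan(dih.phi[:, 0]))
        assert np.all(np.isnan(dih.psi[:, -1]))
        assert np.all(np.isfinite(dih.phi[:, 1:]))

    def test_mirroring_flips_every_sign(self, alpha_right):
        dih = backbone_dihedrals(alpha_right)
        mdih = backbone_dihedrals(mirror(alpha_right))
        np.testing.assert_allclose(mdih.phi, -dih.phi, atol=1e-9)
        np.testing.assert_allclose(mdih.psi, -dih.psi, atol=1e-9)

    def test_against_mdtraj_oracle(self, tmp_path, alpha_right):
        import mdtraj

        path = tmp_path / "helix.pdb"
        write_pdb_ensemble(alpha_right, path)
        traj = mdtraj.load(str(path))
        _, phi = mdtraj.compute_phi(traj)
        _, psi = mdtraj.compute_psi(traj)
        dih = backbone_dihedrals(alpha_right)
        # PDB coordinates carry 3 decimals, so allow 0.1 degree of round-off
        np.testing.assert_allclose(np.degrees(phi), dih.phi[:, 1:], atol=0.1)
        np.testing.assert_allclose(np.degrees(psi), dih.psi[:, :-1], atol=0.1)

    def test_missing_atom_raises(self, alpha_right):
        broken = Ensemble(alpha_right.coords[:, :-2],
                          alpha_right.atom_names[:-2],
                          alpha_right.atom_res[:-2], alpha_right.res_names)
        with pytest.raises(TopologyError):
            backbone_dihedrals(broken)


class TestRegions:
    @pytest.mark.parametrize("phi,psi,region", [
        (-57.0, -47.0, "alpha_R"),
        (57.0, 47.0, "alpha_L"),
        (-49.0, -26.0, "three10_R"),  # 3_10 precedes alpha
        (49.0, 26.0, "three10_L"),
        (-120.0, 130.0, "beta"),
        (-75.0, 145.0, "ppII"),
        (100.0, -100.0, "other"),
    ])
    def test_boxes(self, phi, psi, region):
        assert classify_region(phi, psi) == region

    def test_mirror_maps_regions(self, alpha_right):
        dih = backbone_dihedrals(alpha_right)
        mdih = backbone_dihedrals(mirror(alpha_right))
        phi, psi = dih.phi[0, 4], dih.psi[0, 4]
        assert classify_region(phi, psi) == "alpha_R"
        assert classify_region(mdih.phi[0, 4], mdih.psi[0, 4]) == "alpha_L"


class TestFreeEnergy:
    def test_uniform_sample_is_flat(self):
        rng = np.random.default_rng(0)
        phi = rng.uniform(-180, 180, 40000)
        psi = rng.uniform(-180, 180, 40000)
        grid = rama_free_energy(phi, psi, bins=6, T=300.0)
        assert np.nanmin(grid.delta_g) == 0.0
        assert np.nanmax(grid.delta_g) < 0.1  # sampling noise only

    def test_two_state_free_energy_difference(self):
        """Occupancies 0.8/0.2 at 300 K differ by -RT ln(0.25) = 0.827 kcal/mol."""
        phi = np.concatenate([np.full(800, -57.0), np.full(200, 57.0)])
        psi = np.concatenate([np.full(800, -47.0), np.full(200, 47.0)])
        grid = rama_free_energy(phi, psi, bins=72, T=300.0)
        occupied = np.sort(grid.delta_g[~grid.mask])
        assert occupied[0] == 0.0
        expected = -R_KCAL * 300.0 * np.log(0.25)
        assert occupied[1] == pytest.approx(expected, abs=1e-3)
        assert expected == pytest.approx(0.827, abs=1e-3)

    def test_duplicating_the_sample_changes_nothing(self):
        rng = np.random.default_rng(1)
        phi = rng.normal(-57, 10, 500)
        psi = rng.normal(-47, 10, 500)
        g1 = rama_free_energy(phi, psi, bins=36)
        g2 = rama_free_energy(np.tile(phi, 2), np.tile(psi, 2), bins=36)
        np.testing.assert_allclose(g1.delta_g, g2.delta_g, equal_nan=True)

    def test_jittered_helix_minimum_bin_contains_canonical_angles(self):
        ens = generate_helix_ensemble(HelixSimConfig(
            n_residues=8, helix_type="three10", handedness="right",
            jitter_sigma=15.0, n_frames=500, seed=7))
        dih = backbone_dihedrals(ens)
        grid = rama_free_energy(dih.phi[:, 4], dih.psi[:, 4], bins=24)
        i, j = grid.minimum_bin()
        assert grid.xedges[i] <= -49.0 <= grid.xedges[i + 1]
        assert grid.yedges[j] <= -26.0 <= grid.yedges[j + 1]

    def test_terminal_residue_rejected(self):
        with pytest.raises(ValueError):
            rama_free_energy(np.array([np.nan]), np.array([np.nan]))

    def test_fes_2d_single_bin_and_two_clusters(self):
        x = np.zeros(10)
        grid = fes_2d(x, x, bins=5)
        assert np.nansum(grid.delta_g == 0.0) == 1
        assert grid.mask.sum() == 24
        x = np.concatenate([np.zeros(900), np.ones(100)])
        grid = fes_2d(x, x, bins=2, T=300.0)
        occupied = np.sort(grid.delta_g[~grid.mask])
        assert occupied[1] == pytest.approx(-R_KCAL * 300.0 * np.log(1 / 9), abs=1e-3)
        assert occupied[1] == pytest.approx(1.310, abs=1e-3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fes_2d(np.zeros(3), np.zeros(4))


class TestHBonds:
    def test_ideal_310_yields_only_i3_bonds(self):
        for handed in ("right", "left"):
            ens = generate_helix_ensemble(HelixSimConfig(
                n_residues=10, helix_type="three10", handedness=handed, n_frames=2))
            bonds = detect_hbonds(ens)
            assert bonds, "expected H-bonds in an ideal 3_10 helix"
            assert {b.turn_class for b in bonds} == {"i+3_310"}
            assert all(b.donor - b.acceptor == 3 for b in bonds)
            assert all(b.fraction == 1.0 for b in bonds)
            assert all(2.5 < b.mean_distance <= 3.0 for b in bonds)

    def test_ideal_alpha_yields_only_i4_bonds(self, alpha_right):
        bonds = detect_hbonds(alpha_right)
        assert bonds and {b.turn_class for b in bonds} == {"i+4_alpha"}

    def test_left_310_helix_joint_classification(self, three10_left):
        """Left-handed 3_10 structure coexists with i+3 -> i bonding."""
        bonds = detect_hbonds(three10_left)
        assert {b.turn_class for b in bonds} == {"i+3_310"}
        dih = backbone_dihedrals(three10_left)
        interior = [classify_region(dih.phi[0, r], dih.psi[0, r])
                    for r in range(2, 7)]
        assert set(interior) <= {"three10_L", "alpha_L"}

    def test_gamma_turn_classification(self):
        """An explicit i+2 -> i contact classifies as a gamma turn."""
        far = 50.0
        atoms = []  # (res, name, xyz)
        atoms += [(1, "N", (-3, 3, 0)), (1, "CA", (-2, 2, 0)), (1, "C", (-1, 1, 0)),
                  (1, "O", (0.0, 0.0, 0.0))]
        atoms += [(2, "N", (far, 0, 0)), (2, "CA", (far + 1, 0, 0)),
                  (2, "C", (far + 2, 0, 0)), (2, "O", (far + 3, 0, 0)),
                  (2, "H", (far, 1, 0))]
        # donor N(3) 2.9 A from O(1), H on the N-O axis (angle 180)
        atoms += [(3, "N", (2.9, 0, 0)), (3, "CA", (3.9, 1, 0)),
                  (3, "C", (4.9, 1, 0)), (3, "O", (5.9, 1, 0)),
                  (3, "H", (1.89, 0.0, 0.0))]
        coords = np.array([[xyz for _, _, xyz in atoms]], dtype=float)
        ens = Ensemble(coords, tuple(n for _, n, _ in atoms),
                       tuple(r for r, _, _ in atoms), ("AIB", "AIB", "AIB"))
        bonds = detect_hbonds(ens)
        assert len(bonds) == 1
        assert bonds[0].turn_class == "i+2_gamma"
        assert (bonds[0].acceptor, bonds[0].donor) == (1, 3)

    def test_proline_never_donates(self, three10_left):
        names = tuple("PRO" if i == 5 else n
                      for i, n in enumerate(three10_left.res_names))
        ens = Ensemble(three10_left.coords, three10_left.atom_names,
                       three10_left.atom_res, names)
        assert all(b.donor != 6 for b in detect_hbonds(ens))

    def test_missing_h_without_reconstruction(self, alpha_right):
        with pytest.raises(TopologyError):
            detect_hbonds(alpha_right, reconstruct_h=False)


class TestRmsdRog:
    def test_identical_frames_have_zero_rmsd(self, alpha_right):
        coords = np.repeat(alpha_right.coords[:1], 4, axis=0)
        ens = Ensemble(coords, alpha_right.atom_names, alpha_right.atom_res,
                       alpha_right.res_names)
        np.testing.assert_allclose(rmsd_to_average(ens), 0.0, atol=1e-9)

    def test_rigid_motion_invariance(self, alpha_right):
        from scipy.spatial.transform import Rotation

        base = alpha_right.coords[0]
        rng = np.random.default_rng(3)
        frames = [base]
        for _ in range(3):
            R = Rotation.random(rng=rng).as_matrix()
            frames.append(base @ R.T + rng.uniform(-20, 20, 3))
        ens = Ensemble(np.stack(frames), alpha_right.atom_names,
                       alpha_right.atom_res, alpha_right.res_names)
        np.testing.assert_allclose(rmsd_to_average(ens), 0.0, atol=1e-8)
        np.testing.assert_allclose(rog_series(ens), rog_series(ens)[0], atol=1e-8)

    def test_two_frame_displacement_against_brute_force(self, alpha_right):
        """Independent oracle: centred Kabsch via scipy on the same frames."""
        from scipy.spatial.transform import Rotation

        sel = alpha_right.select(("N", "CA", "C"))
        f0 = alpha_right.coords[0, sel]
        f1 = f0.copy()
        f1[4] += np.array([0.0, 0.0, 0.8])
        frames = np.stack([f0, f1])
        names = tuple(alpha_right.atom_names[i] for i in sel)
        res = tuple(alpha_right.atom_res[i] for i in sel)
        ens = Ensemble(frames[:, :, :], names, res, alpha_right.res_names)
        got = rmsd_to_average(ens)

        def align(X, ref):
            Xc = X - X.mean(0)
            refc = ref - ref.mean(0)
            R, _ = Rotation.align_vectors(refc, Xc)
            return Xc @ R.as_matrix().T

        A = [f - f.mean(0) for f in frames]
        A = [align(f, A[0]) for f in A]
        avg = np.mean(A, axis=0)
        A = [align(f, avg) for f in A]
        avg = np.mean(A, axis=0)
        expected = [np.sqrt(np.mean(np.sum((f - avg) ** 2, axis=1))) for f in A]
        np.testing.assert_allclose(got, expected, atol=1e-6)
        assert got[0] > 0

    def test_insufficient_frames(self, alpha_right):
        ens = Ensemble(alpha_right.coords[:1], alpha_right.atom_names,
                       alpha_right.atom_res, alpha_right.res_names)
        with pytest.raises(InsufficientEnsembleError):
            rmsd_to_average(ens)

    def test_radius_of_gyration_closed_forms(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0
        two = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        assert radius_of_gyration(two) == pytest.approx(0.5)

    def test_radius_of_gyration_direct_formula(self):
        rng = np.random.default_rng(8)
        cloud = rng.normal(size=(50, 3))
        com = cloud.mean(axis=0)
        expected = np.sqrt(np.mean(np.sum((cloud - com) ** 2, axis=1)))
        assert radius_of_gyration(cloud) == pytest.approx(expected, abs=1e-10)

    def test_empty_selection(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((0, 3)))


class TestPdbIO:
    def test_round_trip(self, tmp_path, three10_left):
        path = tmp_path / "ens.pdb"
        write_pdb_ensemble(three10_left, path)
        back = read_pdb_ensemble(path)
        assert back.n_frames == three10_left.n_frames
        assert back.atom_names == three10_left.atom_names
        assert back.res_names == three10_left.res_names
        np.testing.assert_allclose(back.coords, three10_left.coords, atol=1e-3)
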