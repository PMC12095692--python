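"""Contact fingerprints, bound-frame filtering, density grids, clustering."""

import numpy as np
import pytest

from leadscope.epitope_mapper import (ContactFingerprint, Trajectory,
                                      canonicalize_fingerprints,
                                      cluster_fingerprints, contact_fingerprint,
                                      density_grid, epitope_report,
                                      filter_bound_frames, load_trajectory,
                                      superpose, trajectory_fingerprints,
                                      write_dx)
from leadscope.synthetic_data import build_helix_bundle, gen_trajectory

from _oracles import brute_force_contacts


class TestContacts:
    def test_strict_cutoff_boundary(self):
        prot = np.array([[3.99, 0, 0], [4.0, 0, 1000.0]])
        labels = [("A", 1), ("A", 2)]
        fp = contact_fingerprint(np.array([[0.0, 0, 0]]), prot, labels)
        assert fp.residues == frozenset({("A", 1)})
        fp2 = contact_fingerprint(np.array([[0.0, 0, 0]]),
                                  np.array([[4.0, 0, 0]]), [("A", 1)])
        assert fp2.residues == frozenset()

    def test_distant_ligand_has_empty_fingerprint(self):
        bundle = build_helix_bundle()
        fp = contact_fingerprint(np.array([[500.0, 0, 0]]), bundle.coords,
                                 bundle.atom_residues)
        assert fp.residues == frozenset()

    def test_matches_brute_force_on_random_frames(self):
        rng = np.random.default_rng(42)
        prot = rng.uniform(-15, 15, size=(200, 3))
        labels = [("A", int(i // 4)) for i in range(200)]
        for _ in range(10):
            lig = rng.uniform(-18, 18, size=(6, 3))
            fp = contact_fingerprint(lig, prot, labels)
            assert fp.residues == brute_force_contacts(lig, prot, labels)


class TestBoundFrameFilter:
    def test_five_residue_boundary(self):
        fps = [
            ContactFingerprint(0, frozenset({("A", i) for i in range(5)})),
            ContactFingerprint(1, frozenset({("A", i) for i in range(4)})),
        ]
        assert filter_bound_frames(fps, min_residues=5) == [0]

    def test_unbound_trajectory_yields_nothing(self):
        traj, _ = gen_trajectory(n_frames=20, epitope_specs=[], seed=0)
        fps = trajectory_fingerprints(traj)
        assert filter_bound_frames(fps) == []

    def test_planted_bound_frames_recovered_exactly(self):
        traj, manifest = gen_trajectory(n_frames=300, seed=7)
        fps = trajectory_fingerprints(traj)
        bound = set(filter_bound_frames(fps))
        planted = {i for e in manifest["epitopes"] for i in e["frames"]}
        assert bound == planted


class TestSuperposition:
    def test_recovers_random_rigid_motion(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(30, 3))
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-5, 5, 3)
        mobile = ref @ R.T + t
        R_fit, t_fit = superpose(mobile, ref)
        assert np.allclose(mobile @ R_fit.T + t_fit, ref, atol=1e-9)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            superpose(line, line)


class TestDensityGrid:
    def _static_traj(self, lig_pos, n_frames=10):
        bundle = build_helix_bundle()
        lig = np.tile(np.asarray(lig_pos, float)[None, None, :], (n_frames, 1, 1))
        return Trajectory(
            ligand_coords=lig,
            protein_coords=np.broadcast_to(
                bundle.coords, (n_frames,) + bundle.coords.shape).copy(),
            atom_residues=bundle.atom_residues,
            ca_mask=bundle.ca_mask,
        )

    def test_fixed_atom_fills_one_voxel(self):
        traj = self._static_traj([3.3, 2.2, 1.1])
        grid = density_grid(traj, list(range(10)), spacing=1.0)
        assert grid.total == 10
        assert (grid.counts > 0).sum() == 1
        assert grid.counts.max() == 10

    def test_identity_symmetry_leaves_grid_unchanged(self):
        traj = self._static_traj([3.3, 2.2, 1.1])
        plain = density_grid(traj, list(range(10)), spacing=1.0)
        ident = density_grid(traj, list(range(10)), spacing=1.0,
                             symmetry_ops=[(np.eye(3), np.zeros(3))])
        assert np.array_equal(plain.counts, ident.counts)
        assert np.allclose(plain.origin, ident.origin)

    def test_total_counts_conserved_under_folding(self):
        traj, _ = gen_trajectory(n_frames=120, seed=3)
        fps = trajectory_fingerprints(traj)
        bound = filter_bound_frames(fps)
        c2 = (np.diag([-1.0, -1.0, 1.0]), np.zeros(3))
        plain = density_grid(traj, bound, spacing=1.0)
        folded = density_grid(traj, bound, spacing=1.0, symmetry_ops=[c2])
        expected = len(bound) * traj.ligand_coords.shape[1]
        assert plain.total == expected
        assert folded.total == expected

    def test_two_fold_folding_matches_explicit_transform(self):
        # two mirror-image sites related by the C2 operator collapse onto one
        bundle = build_helix_bundle()
        n = 6
        p = np.array([6.0, 2.0, 3.0])
        c2 = (np.diag([-1.0, -1.0, 1.0]), np.zeros(3))
        lig = np.empty((2 * n, 1, 3))
        lig[:n, 0] = p
        lig[n:, 0] = c2[0] @ p  # the symmetric image
        traj = Trajectory(
            ligand_coords=lig,
            protein_coords=np.broadcast_to(
                bundle.coords, (2 * n,) + bundle.coords.shape).copy(),
            atom_residues=bundle.atom_residues,
            ca_mask=bundle.ca_mask,
        )
        folded = density_grid(traj, list(range(2 * n)), spacing=1.0,
                              symmetry_ops=[c2])
        # explicit arithmetic: both images map to one canonical point
        images = np.stack([p, c2[0] @ p])
        canon = images[np.lexsort((images[:, 2], images[:, 1], images[:, 0]))[0]]
        assert folded.total == 2 * n
        assert (folded.counts > 0).sum() == 1
        idx = tuple(np.floor((canon - folded.origin) / 1.0).astype(int))
        assert folded.counts[idx] == 2 * n

    def test_dx_output_roundtrips_header(self, tmp_path):
        traj = self._static_traj([1.0, 2.0, 3.0])
        grid = density_grid(traj, list(range(10)), spacing=0.5)
        out = tmp_path / "density.dx"
        write_dx(grid, out)
        text = out.read_text()
        nx, ny, nz = grid.counts.shape
        assert f"gridpositions counts {nx} {ny} {nz}" in text
        assert f"items {nx * ny * nz}" in text


class TestClustering:
    def test_two_disjoint_residue_sets_separate(self):
        a = frozenset({("A", i) for i in range(5)})
        b = frozenset({("B", i) for i in range(5)})
        fps = [ContactFingerprint(i, a if i % 2 == 0 else b) for i in range(20)]
        clusters = cluster_fingerprints(fps)
        assert len(clusters) == 2
        members = [{fps[i].residues for i in c} for c in clusters]
        assert members[0] in ({a}, {b}) and members[1] in ({a}, {b})

    def test_identical_fingerprints_form_one_cluster(self):
        fp = frozenset({("A", 1), ("A", 2)})
        fps = [ContactFingerprint(i, fp) for i in range(8)]
        assert cluster_fingerprints(fps) == [list(range(8))]

    def test_noisy_planted_partition_recovery(self):
        rng = np.random.default_rng(11)
        sets = [frozenset({("A", i) for i in range(1, 8)}),
                frozenset({("B", i) for i in range(1, 8)}),
                frozenset({("C", i) for i in range(1, 8)})]
        universe = sorted({r for s in sets for r in s})
        fps, truth = [], []
        for k in range(90):
            e = k % 3
            residues = set(sets[e])
            for r in universe:  # 5% flip noise on each residue bit
                if rng.random() < 0.05:
                    residues ^= {r}
            fps.append(ContactFingerprint(k, frozenset(residues)))
            truth.append(e)
        clusters = cluster_fingerprints(fps)
        # map each recovered cluster to its majority planted epitope
        correct = 0
        for members in clusters:
            labels = [truth[i] for i in members]
            correct += max(labels.count(v) for v in set(labels))
        assert correct / len(fps) >= 0.9

    def test_chain_canonicalization_merges_symmetric_epitopes(self):
        a = frozenset({("A", i) for i in range(5)})
        c = frozenset({("C", i) for i in range(5)})
        fps = [ContactFingerprint(0, a), ContactFingerprint(1, c)]
        canon = canonicalize_fingerprints(fps, {"C": "A", "D": "B"})
        assert canon[0].residues == canon[1].residues


class TestEpitopeReport:
    def _fps(self, n, size=5):
        return [ContactFingerprint(i, frozenset({("A", j) for j in range(size)}))
                for i in range(n)]

    def test_occupancy_as_fraction_of_all_frames(self):
        fps = self._fps(132)
        report = epitope_report(1000, fps, [list(range(132))])
        assert report.clusters[0].occupancy_pct == pytest.approx(13.2)

    def test_two_clusters_ordered_by_occupancy(self):
        fps = self._fps(132) + [
            ContactFingerprint(132 + i, frozenset({("B", j) for j in range(5)}))
            for i in range(101)]
        clusters = [list(range(132)), list(range(132, 233))]
        report = epitope_report(1000, fps, clusters)
        assert [c.occupancy_pct for c in report.clusters] == pytest.approx([13.2, 10.1])

    def test_empty_report(self):
        report = epitope_report(100, [], [])
        assert report.clusters == [] and report.n_bound == 0

    def test_occupancy_invariant_to_frame_order_and_sums(self):
        fps = self._fps(40)
        clusters = [list(range(25)), list(range(25, 40))]
        rep = epitope_report(200, fps, clusters)
        total = sum(c.occupancy_pct for c in rep.clusters)
        assert total == pytest.approx(100.0 * 40 / 200)
        shuffled = list(reversed(fps))
        rep2 = epitope_report(200, shuffled,
                              [list(range(15)), list(range(15, 40))])
        assert sum(c.occupancy_pct for c in rep2.clusters) == pytest.approx(total)

    def test_hot_spot_flagging(self):
        fps = [ContactFingerprint(0, frozenset({("A", 498), ("A", 502),
                                                ("A", 505), ("A", 509),
                                                ("A", 523)}))]
        rep = epitope_report(10, fps, [[0]],
                             hot_spots=[("A", 498), ("A", 502), ("A", 540)])
        assert rep.clusters[0].hot_spot_residues == [("A", 498), ("A", 502)]

    def test_bound_denominator_option(self):
        fps = self._fps(50)
        rep = epitope_report(1000, fps, [list(range(50))], denominator="bound")
        assert rep.clusters[0].occupancy_pct == pytest.approx(100.0)


class TestTrajectoryIO:
    def test_pdb_roundtrip_preserves_contacts(self, tmp_path):
        path = tmp_path / "traj.pdb"
        traj, manifest = gen_trajectory(n_frames=30, seed=5, out_pdb=path)
        loaded = load_trajectory(path, ligand_resname="LIG")
        assert loaded.n_frames == traj.n_frames
        fps_mem = trajectory_fingerprints(traj)
        fps_load = trajectory_fingerprints(loaded)
        for a, b in zip(fps_mem, fps_load):
            assert a.residues == b.residues
        assert (tmp_path / "traj.manifest.json").exists()

    def test_missing_ligand_resname_rejected(self, tmp_path):
        path = tmp_path / "traj.pdb"
        gen_trajectory(n_frames=5, seed=5, out_pdb=path)
        with pytest.raises(ValueError, match="resname"):
            load_trajectory(path, ligand_resname="XXX")
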