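"""Contact fingerprints, symmetry canonicalization, epitope clustering,
occupancy grids."""

import numpy as np
import pytest

from oligobind.contacts import (FrameContacts, SymmetryMap, canonicalize,
                                cluster_epitopes, contact_fingerprint,
                                filter_frames, jaccard_distance_matrix,
                                occupancy_grid, superpose_frames)
from oligobind.synthetic import gen_contact_trajectory


def brute_force_fingerprint(lig, residues, cutoff):
    bits = np.zeros(len(residues), dtype=bool)
    for ri, res in enumerate(residues):
        for a in np.asarray(res).reshape(-1, 3):
            for b in np.asarray(lig).reshape(-1, 3):
                if np.linalg.norm(a - b) < cutoff:
                    bits[ri] = True
    return bits


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


class TestContactFingerprint:
    def test_far_ligand_all_zero(self):
        residues = [np.array([[0.0, 0.0, 0.0]]), np.array([[3.0, 0.0, 0.0]])]
        fp = contact_fingerprint(np.array([[100.0, 0.0, 0.0]]), residues)
        assert fp.n_contacts == 0

    def test_single_pair_within_cutoff(self):
        residues = [np.array([[0.0, 0.0, 0.0]]), np.array([[50.0, 0.0, 0.0]])]
        fp = contact_fingerprint(np.array([[3.9, 0.0, 0.0]]), residues)
        assert fp.contacts.tolist() == [True, False]
        fp2 = contact_fingerprint(np.array([[4.05, 0.0, 0.0]]), residues)
        assert fp2.n_contacts == 0

    def test_matches_brute_force_oracle(self, rng):
        residues = [rng.uniform(-10, 10, (3, 3)) for _ in range(12)]
        for i in range(50):
            lig = rng.uniform(-12, 12, (4, 3))
            fp = contact_fingerprint(lig, residues, 4.0, frame_index=i)
            assert fp.contacts.tolist() == \
                brute_force_fingerprint(lig, residues, 4.0).tolist()

    def test_rigid_motion_invariance(self, rng):
        residues = [rng.uniform(-8, 8, (2, 3)) for _ in range(10)]
        lig = rng.uniform(-8, 8, (3, 3))
        R = random_rotation(rng)
        t = rng.uniform(-50, 50, 3)
        fp0 = contact_fingerprint(lig, residues)
        fp1 = contact_fingerprint(lig @ R.T + t,
                                  [r @ R.T + t for r in residues])
        assert fp0.contacts.tolist() == fp1.contacts.tolist()

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            contact_fingerprint(np.empty((0, 3)), [np.zeros((1, 3))])
        with pytest.raises(ValueError):
            contact_fingerprint(np.zeros((1, 3)), [])


class TestFilterFrames:
    def test_popcount_threshold(self):
        def frame(n_set):
            bits = np.zeros(20, dtype=bool)
            bits[:n_set] = True
            return FrameContacts(0, bits)

        assert filter_frames([frame(4)]) == []
        assert len(filter_frames([frame(5)])) == 1

    def test_zero_threshold_identity(self):
        frames = [FrameContacts(i, np.zeros(10, dtype=bool)) for i in range(3)]
        assert len(filter_frames(frames, min_residues=0)) == 3

    def test_all_unbound_empty(self):
        frames = [FrameContacts(i, np.zeros(10, dtype=bool)) for i in range(5)]
        assert filter_frames(frames) == []


class TestSymmetry:
    def test_group_is_closed_and_order_four(self):
        sym = SymmetryMap.dimer_of_dimers(3)
        assert len(sym.permutations) == 4
        keys = {p.tobytes() for p in sym.permutations}
        for p in sym.permutations:
            for q in sym.permutations:
                assert p[q].tobytes() in keys

    def test_non_bijection_rejected(self):
        with pytest.raises(ValueError):
            SymmetryMap([np.array([0, 0, 1])])

    def test_chain_swapped_frames_canonicalize_together(self):
        sym = SymmetryMap.dimer_of_dimers(5)
        bits_a = np.zeros(20, dtype=bool)
        bits_a[[1, 2, 3]] = True          # epitope on chain A
        for perm in sym.permutations[1:]:
            image = np.zeros(20, dtype=bool)
            image[perm[np.flatnonzero(bits_a)]] = True
            # note: apply inverse mapping to place epitope on another chain
            frames = canonicalize([FrameContacts(0, bits_a),
                                   FrameContacts(1, bits_a[perm])], sym)
            assert frames[0].contacts.tolist() == frames[1].contacts.tolist()

    def test_symmetric_fixed_point_unchanged(self):
        sym = SymmetryMap.dimer_of_dimers(4)
        bits = np.zeros(16, dtype=bool)
        bits[[0, 4, 8, 12]] = True  # same residue on every chain
        out = canonicalize([FrameContacts(0, bits)], sym)
        assert out[0].contacts.tolist() == bits.tolist()

    def test_idempotent(self, toy_trajectory):
        traj, _ = toy_trajectory
        fps = [contact_fingerprint(l, traj.protein_coords_by_residue,
                                   frame_index=i)
               for i, l in enumerate(traj.ligand_frames)]
        fps = filter_frames(fps)
        sym = traj.symmetry_map()
        once = canonicalize(fps, sym)
        twice = canonicalize(once, sym)
        for a, b in zip(once, twice):
            assert a.contacts.tolist() == b.contacts.tolist()

    def test_canonicalization_never_increases_symmetry_distance(self, rng):
        sym = SymmetryMap.dimer_of_dimers(6)
        for _ in range(20):
            bits = rng.random(24) < 0.3
            perm = sym.permutations[rng.integers(4)]
            a, b = FrameContacts(0, bits), FrameContacts(1, bits[perm])
            ca, cb = canonicalize([a, b], sym)
            d_after = np.logical_xor(ca.contacts, cb.contacts).sum()
            assert d_after == 0  # symmetry mates collapse exactly

    def test_length_mismatch_rejected(self):
        sym = SymmetryMap.dimer_of_dimers(4)
        with pytest.raises(ValueError):
            canonicalize([FrameContacts(0, np.zeros(10, dtype=bool))], sym)


class TestClustering:
    def test_identical_fingerprints_single_cluster(self):
        bits = np.zeros(16, dtype=bool)
        bits[:6] = True
        frames = [FrameContacts(i, bits) for i in range(4)]
        res = cluster_epitopes(frames)
        assert res.n_clusters == 1

    def test_disjoint_fingerprints_separate(self):
        a = np.zeros(16, dtype=bool)
        b = np.zeros(16, dtype=bool)
        a[:5], b[8:13] = True, True
        res = cluster_epitopes([FrameContacts(0, a), FrameContacts(1, b)])
        assert res.n_clusters == 2

    def test_single_frame_singleton(self):
        bits = np.ones(8, dtype=bool)
        res = cluster_epitopes([FrameContacts(0, bits)])
        assert res.n_clusters == 1 and res.sizes == {1: 1}

    def test_planted_epitope_recovery(self, toy_trajectory):
        traj, truth = toy_trajectory
        fps = [contact_fingerprint(l, traj.protein_coords_by_residue,
                                   frame_index=i)
               for i, l in enumerate(traj.ligand_frames)]
        kept = filter_frames(fps)
        canon = canonicalize(kept, traj.symmetry_map())
        res = cluster_epitopes(canon)
        labels_true = truth["labels"][[f.frame_index for f in kept]]
        correct = 0
        for c in res.top_clusters(3):
            _, counts = np.unique(labels_true[res.labels == c],
                                  return_counts=True)
            correct += counts.max()
        assert correct / len(kept) >= 0.95

    def test_jaccard_matrix_properties(self, rng):
        frames = [FrameContacts(i, rng.random(30) < 0.3) for i in range(25)]
        D = jaccard_distance_matrix(frames)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        for _ in range(100):
            i, j, k = rng.integers(25, size=3)
            assert D[i, k] <= D[i, j] + D[j, k] + 1e-12


class TestOccupancyGrid:
    def test_single_atom_single_voxel(self):
        ref = np.array([[0.0, 0.0, 0.0], [2.0, 2.0, 2.0]])
        g = occupancy_grid([np.array([[1.0, 1.0, 1.0]])], ref, spacing=0.5)
        assert g.counts.sum() == 1
        assert g.counts.max() == 1
        assert g.n_contact_frames == 1

    def test_no_contact_frames_empty(self):
        ref = np.zeros((1, 3))
        g = occupancy_grid([], ref)
        assert g.counts.sum() == 0 and g.n_contact_frames == 0

    def test_matches_brute_force_binning(self, rng):
        ref = rng.uniform(-5, 5, (20, 3))
        frames = [rng.uniform(-8, 8, (3, 3)) for _ in range(20)]
        g = occupancy_grid(frames, ref, spacing=0.5)
        brute = np.zeros_like(g.counts)
        for f in frames:
            for atom in f:
                idx = np.floor((atom - g.origin) / g.spacing).astype(int)
                idx = np.minimum(idx, np.array(brute.shape) - 1)
                brute[tuple(idx)] += 1
        assert (g.counts == brute).all()
        assert g.counts.sum() == 60  # count conservation

    def test_auto_expansion_preserves_counts(self):
        ref = np.zeros((1, 3))
        far = np.array([[40.0, 0.0, 0.0]])
        g = occupancy_grid([far], ref, spacing=0.5)
        assert g.counts.sum() == 1

    def test_superpose_then_grid_rigid_invariance(self, rng):
        ref = rng.uniform(-5, 5, (12, 3))
        lig = [rng.uniform(-6, 6, (3, 3)) for _ in range(5)]
        g0 = occupancy_grid(lig, ref, spacing=1.0)
        R = random_rotation(rng)
        t = rng.uniform(-20, 20, 3)
        moved_prot = [ref @ R.T + t] * 5
        moved_lig = [l @ R.T + t for l in lig]
        back = superpose_frames(moved_prot, moved_lig, ref)
        g1 = occupancy_grid(back, ref, spacing=1.0)
        assert (g0.counts == g1.counts).all()

    def test_dx_export_roundtrip(self, tmp_path):
        from gridData import Grid
        ref = np.array([[0.0, 0.0, 0.0], [3.0, 3.0, 3.0]])
        g = occupancy_grid([np.array([[1.2, 1.2, 1.2]])], ref, spacing=0.5)
        path = tmp_path / "occ.dx"
        g.to_dx(path)
        loaded = Grid(str(path))
        assert loaded.grid.sum() == pytest.approx(1.0)
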