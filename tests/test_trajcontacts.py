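"""RMSD matrices, average-linkage clustering, contact fingerprints —
each checked against a naive reference implementation on small fixtures."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_trajectory
from gpcrbias.errors import ContractError, MalformedTrajectoryError, MissingAnnotationError
from gpcrbias.trajcontacts import (
    ContactFingerprint,
    RmsdMatrix,
    Trajectory,
    average_linkage_cluster,
    contact_frequency,
    ecl2_accumulated,
    ligand_rmsd_matrix,
    report_contacts,
)


# ---------------------------------------------------------------- oracles

def naive_rmsd_matrix(lig_coords: np.ndarray) -> np.ndarray:
    """Double-loop pairwise RMSD, no vectorization."""
    n = lig_coords.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for a in range(lig_coords.shape[1]):
                d = lig_coords[i, a] - lig_coords[j, a]
                acc += d @ d
            out[i, j] = np.sqrt(acc / lig_coords.shape[1])
    return out


def naive_average_linkage(dist: np.ndarray, cutoff: float) -> set[frozenset]:
    """O(n^3) agglomeration: repeatedly merge the pair of clusters with the
    smallest unweighted average inter-cluster distance until it exceeds
    the cutoff; returns the partition as a set of frozensets."""
    clusters = [{i} for i in range(dist.shape[0])]
    while len(clusters) > 1:
        best, best_d = None, np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if d < best_d:
                    best, best_d = (i, j), d
        if best_d > cutoff:
            break
        i, j = best
        clusters[i] |= clusters[j]
        del clusters[j]
    return {frozenset(c) for c in clusters}


def naive_contact_frequencies(traj: Trajectory, frames, distance: float) -> dict:
    """Per-frame, per-pair distance scan."""
    lig_idx = np.nonzero(traj.mask("ligand"))[0]
    rec_idx = np.nonzero(traj.mask("receptor"))[0]
    res_of = traj.atoms["residue_id"].to_numpy()
    freqs: dict[int, int] = {}
    residues = sorted({int(res_of[i]) for i in rec_idx})
    for r in residues:
        hits = 0
        for f in frames:
            found = False
            for i in rec_idx:
                if res_of[i] != r:
                    continue
                for j in lig_idx:
                    if np.linalg.norm(traj.coords[f, i] - traj.coords[f, j]) < distance:
                        found = True
            hits += found
        freqs[r] = 100.0 * hits / len(frames)
    return freqs


def partition_of(labels: np.ndarray) -> set[frozenset]:
    return {frozenset(np.nonzero(labels == c)[0].tolist())
            for c in np.unique(labels)}


# ---------------------------------------------------------------- fixtures

def random_fixture(seed: int, n_frames: int = 5, n_lig: int = 4):
    rng = np.random.default_rng(seed)
    lig = rng.uniform(-6, 6, size=(n_frames, n_lig, 3))
    rec_spec = [(1, "R1", ""), (2, "R2", "ECL2"), (3, "R3", "")]
    rec = np.array([[12.0, 0, 0], [0, 12.0, 0], [3.0, 3.0, 8.0]])
    return make_trajectory(lig, rec, rec_spec)


# ---------------------------------------------------------------- tests

class TestRmsdMatrix:
    def test_identical_frames_all_zero(self, square_receptor):
        rec, spec = square_receptor
        lig = np.tile(np.array([[0.0, 0, 0], [1.5, 0, 0]]), (4, 1, 1))
        m = ligand_rmsd_matrix(make_trajectory(lig, rec, spec))
        np.testing.assert_allclose(m.values, 0.0, atol=1e-12)

    def test_rigid_translation_345(self, square_receptor):
        # all ligand atoms moved by (3, 4, 0) in the receptor frame: RMSD 5
        rec, spec = square_receptor
        base = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0]])
        lig = np.stack([base, base + np.array([3.0, 4.0, 0.0])])
        m = ligand_rmsd_matrix(make_trajectory(lig, rec, spec))
        assert m.values[0, 1] == pytest.approx(5.0, abs=1e-12)
        assert m.values[1, 0] == pytest.approx(5.0, abs=1e-12)

    def test_matches_naive_recomputation(self, square_receptor):
        rec, spec = square_receptor
        rng = np.random.default_rng(5)
        lig = rng.uniform(-5, 5, size=(5, 4, 3))
        traj = make_trajectory(lig, rec, spec)
        m = ligand_rmsd_matrix(traj)
        np.testing.assert_allclose(m.values, naive_rmsd_matrix(lig), atol=1e-9)

    def test_rigid_motion_invariance(self, square_receptor):
        """One global rotation+translation applied to every frame changes
        nothing after receptor superposition."""
        rec, spec = square_receptor
        rng = np.random.default_rng(6)
        lig = rng.uniform(-5, 5, size=(4, 3, 3))
        traj = make_trajectory(lig, rec, spec)
        R = Rotation.from_euler("xyz", [20, -35, 110], degrees=True).as_matrix()
        t = np.array([7.0, -3.0, 11.0])
        moved = Trajectory(traj.coords @ R.T + t, traj.atoms)
        m0 = ligand_rmsd_matrix(traj)
        m1 = ligand_rmsd_matrix(moved)
        np.testing.assert_allclose(m1.values, m0.values, atol=1e-9)

    def test_per_frame_motion_undone_by_alignment(self, square_receptor):
        rec, spec = square_receptor
        rng = np.random.default_rng(7)
        lig = rng.uniform(-5, 5, size=(4, 3, 3))
        traj = make_trajectory(lig, rec, spec)
        coords = traj.coords.copy()
        for f in range(1, 4):
            R = Rotation.random(rng=rng).as_matrix()
            coords[f] = coords[f] @ R.T + rng.uniform(-8, 8, 3)
        m0 = ligand_rmsd_matrix(traj)
        m1 = ligand_rmsd_matrix(Trajectory(coords, traj.atoms))
        np.testing.assert_allclose(m1.values, m0.values, atol=1e-8)

    def test_too_few_alignment_atoms(self, square_receptor):
        rec, spec = square_receptor
        lig = np.zeros((2, 2, 3))
        traj = make_trajectory(lig, rec, spec)
        mask = np.zeros(len(traj.atoms), dtype=bool)
        mask[-2:] = True
        with pytest.raises(ContractError):
            ligand_rmsd_matrix(traj, align_selection=mask)

    def test_malformed_trajectory_rejected(self, square_receptor):
        rec, spec = square_receptor
        with pytest.raises(MalformedTrajectoryError):
            make_trajectory(np.full((2, 2, 3), np.nan), rec, spec)


class TestAverageLinkage:
    def test_single_frame(self):
        cl = average_linkage_cluster(RmsdMatrix(np.zeros((1, 1))), 5.0)
        assert cl.labels.tolist() == [1]
        assert cl.main_cluster == 1

    def test_two_well_separated_groups(self):
        # intra < 1 A, inter > 8 A -> exactly two clusters, main = larger
        n1, n2 = 5, 3
        d = np.zeros((n1 + n2, n1 + n2))
        rng = np.random.default_rng(2)
        for i in range(n1 + n2):
            for j in range(i + 1, n1 + n2):
                same = (i < n1) == (j < n1)
                d[i, j] = d[j, i] = rng.uniform(0.2, 0.9) if same else \
                    rng.uniform(8.5, 11.0)
        cl = average_linkage_cluster(RmsdMatrix(d), 5.0)
        assert np.unique(cl.labels).size == 2
        assert set(cl.main_frames.tolist()) == set(range(n1))

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("n", [2, 5, 8])
    def test_matches_naive_dendrogram(self, seed, n):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, size=(n, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        for cutoff in (2.0, 5.0, 8.0):
            cl = average_linkage_cluster(RmsdMatrix(d), cutoff)
            assert partition_of(cl.labels) == naive_average_linkage(d, cutoff)

    def test_main_cluster_tie_broken_by_compactness(self):
        # two 2-frame clusters: sizes tie; frames {2,3} are tighter
        d = np.array([
            [0.0, 1.0, 9.0, 9.0],
            [1.0, 0.0, 9.0, 9.0],
            [9.0, 9.0, 0.0, 0.2],
            [9.0, 9.0, 0.2, 0.0],
        ])
        cl = average_linkage_cluster(RmsdMatrix(d), 5.0)
        assert set(cl.main_frames.tolist()) == {2, 3}


class TestContacts:
    def test_designed_frequencies(self, square_receptor):
        rec, spec = square_receptor
        # residue 1 within 3 A in 3 of 4 frames, residue 2 never
        base = np.array([[0.0, 0, 0]])
        near = np.array([[18.0, 0, 0]])  # 2 A from receptor atom 1 at (20,0,0)
        lig = np.stack([near, near, near, base])
        traj = make_trajectory(lig, rec, spec)
        fp = contact_frequency(traj, np.arange(4))
        assert fp.per_residue[1] == pytest.approx(75.0)
        assert fp.per_residue[2] == 0.0

    def test_matches_naive_scan(self):
        traj = random_fixture(11, n_frames=6)
        frames = np.arange(6)
        fp = contact_frequency(traj, frames, distance=6.0)
        naive = naive_contact_frequencies(traj, frames, 6.0)
        assert set(fp.per_residue) == set(naive)
        for r in naive:
            assert fp.per_residue[r] == pytest.approx(naive[r], abs=1e-9)

    def test_empty_frame_set_rejected(self):
        with pytest.raises(ContractError):
            contact_frequency(random_fixture(1), [])

    def test_frame_permutation_invariance(self):
        traj = random_fixture(13, n_frames=6)
        m = ligand_rmsd_matrix(traj)
        cl = average_linkage_cluster(m, 5.0)
        fp = contact_frequency(traj, cl.main_frames, 6.0)
        perm = np.random.default_rng(0).permutation(6)
        traj_p = Trajectory(traj.coords[perm], traj.atoms)
        m_p = ligand_rmsd_matrix(traj_p)
        cl_p = average_linkage_cluster(m_p, 5.0)
        # permuted frame i is original frame perm[i]; partitions must agree
        # after mapping back to original frame ids
        inv = np.argsort(perm)
        assert partition_of(cl.labels) == {
            frozenset(int(perm[f]) for f in c) for c in partition_of(cl_p.labels)
        }
        fp_p = contact_frequency(traj_p, [int(inv[f]) for f in cl.main_frames], 6.0)
        for r, v in fp.per_residue.items():
            assert fp_p.per_residue[r] == pytest.approx(v)


class TestReportingAndEcl2:
    def test_threshold_is_strict(self):
        fp = ContactFingerprint({1: 50.0, 2: 51.0, 3: 49.9}, {})
        assert [r for r, _ in report_contacts(fp, 50.0)] == [2]

    def test_ordering_by_descending_frequency(self):
        fp = ContactFingerprint({1: 70.0, 2: 95.0, 3: 80.0}, {})
        assert [r for r, _ in report_contacts(fp, 50.0)] == [2, 3, 1]

    def test_empty_fingerprint(self):
        assert report_contacts(ContactFingerprint({}, {}), 50.0) == []

    def test_ecl2_sum_and_additivity(self):
        traj = random_fixture(3)
        fp = ContactFingerprint({1: 60.0, 2: 30.0, 3: 10.0}, {})
        # only residue 2 is tagged ECL2 in the fixture
        assert ecl2_accumulated(fp, traj.atoms) == pytest.approx(30.0)
        atoms2 = traj.atoms.copy()
        atoms2.loc[atoms2["residue_id"] == 3, "loop_tag"] = "ECL2"
        assert ecl2_accumulated(fp, atoms2) == pytest.approx(40.0)

    def test_no_contacts_gives_zero(self):
        traj = random_fixture(4)
        fp = ContactFingerprint({1: 0.0, 2: 0.0, 3: 0.0}, {})
        assert ecl2_accumulated(fp, traj.atoms) == 0.0

    def test_missing_annotation_rejected(self):
        traj = random_fixture(5)
        atoms = traj.atoms.copy()
        atoms["loop_tag"] = ""
        with pytest.raises(MissingAnnotationError):
            ecl2_accumulated(ContactFingerprint({1: 10.0}, {}), atoms)

    def test_designed_ecl2_ordering(self):
        """A ligand designed with heavy loop engagement accumulates more
        ECL2 contact than one designed with light engagement."""
        from gpcrbias.synth import TrajectorySpec, default_pose_centers, simulate_trajectory

        def accumulated(contacts):
            spec = TrajectorySpec(
                8, default_pose_centers(1), (1.0,),
                designed_contacts=contacts,
                loop_tags={"L228": "ECL2", "L229": "ECL2"}, seed=21)
            traj = simulate_trajectory(spec)
            m = ligand_rmsd_matrix(traj)
            cl = average_linkage_cluster(m, 5.0)
            fp = contact_frequency(traj, cl.main_frames)
            return ecl2_accumulated(fp, traj.atoms)

        heavy = accumulated({"L228": 1.0, "L229": 0.75, "D155": 1.0})
        light = accumulated({"L228": 0.25, "L229": 0.0, "D155": 1.0})
        assert heavy == pytest.approx(175.0)
        assert light == pytest.approx(25.0)
        assert heavy > light
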