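"""Frame selection, RMSD, clustering options C/D/E, MCC, model extraction."""
import itertools
import math

import numpy as np
import pytest

from cgfold.cg_model_io import (
    Trajectory,
    TrajectoryFrame,
    make_header,
    read_structure,
    write_trajectory,
    read_trajectory,
)
from oracles import (
    brute_force_d as _brute_force_d,
    brute_force_e as _brute_force_e,
    max_clique_under_diameter as _max_clique_under_diameter,
    planted_matrix as _planted_matrix,
)
from cgfold.trajectory_analysis import (
    Clustering,
    FrameRecord,
    RMSDMatrix,
    cluster_option_c,
    cluster_option_d,
    cluster_option_e,
    extract_models,
    kabsch_rmsd,
    mcc_basepairs,
    raw_rmsd,
    rmsd_matrix,
    select_top_frames,
)


def _traj(energies, n_res=2, replica=0, seed=0, coords=None):
    rng = np.random.default_rng(seed)
    frames = []
    for k, e in enumerate(energies):
        c = coords[k] if coords is not None else rng.normal(0, 5, n_res * 15)
        frames.append(TrajectoryFrame(
            step=(k + 1) * 10, replica=replica, temperature=1.0,
            energy_total=e, energy_terms={"surrogate": e},
            coordinates=np.asarray(c, dtype=float).ravel(),
        ))
    header = make_header(["G" * n_res], ["A"], ["surrogate"], 1, seed)
    return Trajectory(header, frames)


class TestSelectTopFrames:
    def test_percent_selects_lowest_energy(self):
        traj = _traj([5.0, 1.0, 3.0, 0.5, 2.0, 4.0, 2.5, 3.5, 4.5, 1.5])
        top = select_top_frames(traj, 20.0)
        assert [f.energy for f in top] == [0.5, 1.0]

    def test_percent_100_returns_all_sorted(self):
        traj = _traj([3.0, 1.0, 2.0])
        top = select_top_frames(traj, 100.0)
        assert [f.energy for f in top] == [1.0, 2.0, 3.0]

    def test_equal_energies_keep_earlier_frame_first(self):
        traj = _traj([2.0, 2.0, 1.0])
        top = select_top_frames(traj, 100.0)
        assert [f.frame.step for f in top] == [30, 10, 20]

    def test_pooling_multiple_trajectories(self):
        t1 = _traj([3.0, 1.0])
        t2 = _traj([0.5, 2.0], replica=0, seed=1)
        top = select_top_frames([t1, t2], 50.0)
        assert [f.energy for f in top] == [0.5, 1.0]
        assert top[0].run == 1

    def test_bad_percent_rejected(self):
        with pytest.raises(ValueError):
            select_top_frames(_traj([1.0]), 0.0)


class TestRMSD:
    def test_identical_sets_give_zero(self):
        X = np.random.default_rng(0).normal(0, 3, (10, 3))
        assert kabsch_rmsd(X, X) == pytest.approx(0.0, abs=1e-10)
        assert raw_rmsd(X, X) == 0.0

    def test_kabsch_invariant_under_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        X = np.random.default_rng(1).normal(0, 3, (20, 3))
        Y = X @ Rotation.random(random_state=2).as_matrix().T + [4.0, -2.0, 9.0]
        assert kabsch_rmsd(X, Y) < 1e-8
        assert raw_rmsd(X, Y) > 1.0

    def test_pure_translation_raw_equals_shift(self):
        X = np.random.default_rng(3).normal(0, 3, (12, 3))
        Y = X + np.array([3.0, 0.0, 0.0])
        assert raw_rmsd(X, Y) == pytest.approx(3.0, abs=1e-12)
        assert kabsch_rmsd(X, Y) == pytest.approx(0.0, abs=1e-8)

    def test_kabsch_matches_numeric_optimization(self):
        """Oracle: minimize RMSD over rotation vectors numerically."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        X = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        Y = X.copy()
        Y[3] += np.array([1.0, -0.5, 0.7])

        def f(rv):
            R = Rotation.from_rotvec(rv).as_matrix()
            Xr = (X - X.mean(0)) @ R.T
            Yr = Y - Y.mean(0)
            return np.sqrt(((Xr - Yr) ** 2).sum() / len(X))

        best = min(
            (minimize(f, x0, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12}).fun
             for x0 in [np.zeros(3), np.array([0.1, 0.2, -0.1]),
                        np.array([-0.3, 0.1, 0.4])]),
        )
        assert kabsch_rmsd(X, Y) == pytest.approx(best, abs=1e-3)

    def test_reflection_not_allowed(self):
        # a mirrored chiral set cannot be superposed to zero by proper rotations
        X = np.array([[0.0, 0, 0], [1, 0, 0], [0, 2, 0], [0, 0, 3]])
        Y = X * np.array([-1.0, 1.0, 1.0])
        assert kabsch_rmsd(X, Y) > 0.1

    def test_raw_always_at_least_kabsch(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            X = rng.normal(0, 2, (6, 3))
            Y = rng.normal(0, 2, (6, 3))
            assert raw_rmsd(X, Y) >= kabsch_rmsd(X, Y) - 1e-9

    def test_frozen_core_raw_rmsd_reflects_mobile_region(self):
        """With identical frozen beads, raw RMSD equals the mobile-region
        deviation scaled by the square root of the mobile bead fraction."""
        rng = np.random.default_rng(5)
        core = rng.normal(0, 5, (30, 3))
        mobile1 = rng.normal(0, 5, (10, 3))
        mobile2 = mobile1 + rng.normal(0, 1, (10, 3))
        X = np.vstack([core, mobile1])
        Y = np.vstack([core, mobile2])
        expected = math.sqrt(((mobile1 - mobile2) ** 2).sum() / 40)
        assert raw_rmsd(X, Y) == pytest.approx(expected, abs=1e-12)

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            raw_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestRMSDMatrix:
    def test_identical_frames_give_zero_matrix(self):
        c = np.random.default_rng(0).normal(0, 3, 30)
        traj = _traj([1.0, 2.0, 3.0], coords=[c, c, c])
        top = select_top_frames(traj, 100.0)
        M = rmsd_matrix(top, superpose=True)
        assert np.allclose(M.matrix, 0.0, atol=1e-8)

    def test_matrix_survives_trajectory_round_trip(self, tmp_path):
        traj = _traj([3.0, 1.0, 2.0, 5.0])
        top = select_top_frames(traj, 100.0)
        M1 = rmsd_matrix(top, superpose=True)
        p = tmp_path / "t.traj"
        write_trajectory(traj, p)
        top2 = select_top_frames(read_trajectory(p), 100.0)
        M2 = rmsd_matrix(top2, superpose=True)
        assert np.allclose(M1.matrix, M2.matrix, atol=1e-6)

    def test_superposed_entries_never_exceed_raw(self):
        traj = _traj([1.0, 2.0, 3.0, 4.0], seed=9)
        top = select_top_frames(traj, 100.0)
        sup = rmsd_matrix(top, superpose=True).matrix
        raw = rmsd_matrix(top, superpose=False).matrix
        assert (sup <= raw + 1e-9).all()

    def test_backbone_subset_uses_p_and_c4(self):
        rng = np.random.default_rng(11)
        base = rng.normal(0, 5, (2, 5, 3))
        shifted = base.copy()
        shifted[:, 2:, :] += 100.0  # base beads differ wildly, backbone equal
        traj = _traj([1.0, 2.0], coords=[base.ravel(), shifted.ravel()])
        top = select_top_frames(traj, 100.0)
        M = rmsd_matrix(top, superpose=False, subset="backbone")
        assert M.matrix[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            RMSDMatrix([(0, 0, 0), (0, 0, 1)],
                       np.array([[0.0, 1.0], [2.0, 0.0]]), True)


class TestClusteringOracles:
    @pytest.mark.parametrize("sizes", [(4, 3), (6, 2, 2), (3, 3, 3, 2, 2, 1, 1)])
    def test_option_d_matches_brute_force(self, sizes):
        M, energies, _ = _planted_matrix(sizes, seed=hash(sizes) % 1000)
        got = cluster_option_d(M, energies, 5.0)
        want_clusters, want_reps = _brute_force_d(M.matrix, energies, 5.0)
        assert got.clusters == want_clusters
        assert got.representatives == want_reps

    @pytest.mark.parametrize("sizes", [(4, 3), (6, 2, 2), (3, 3, 3, 2, 2, 1, 1)])
    def test_option_e_matches_brute_force(self, sizes):
        M, energies, _ = _planted_matrix(sizes, seed=hash(sizes) % 1000 + 1)
        got = cluster_option_e(M, energies, 5.0)
        want_clusters, want_reps = _brute_force_e(M.matrix, energies, 5.0)
        assert got.clusters == want_clusters
        assert got.representatives == want_reps

    @pytest.mark.parametrize("sizes", [(5, 4), (6, 3, 2), (4, 4, 3, 2, 1)])
    def test_option_c_matches_exhaustive_clique_search(self, sizes):
        M, energies, _ = _planted_matrix(sizes, sep=50.0,
                                         seed=hash(sizes) % 1000 + 2)
        got = cluster_option_c(M, 5.0)
        remaining = list(range(len(M.matrix)))
        for members, rep in zip(got.clusters, got.representatives):
            want = _max_clique_under_diameter(M.matrix, remaining, 5.0)
            assert sorted(members) == sorted(want)
            medoid = min(members,
                         key=lambda p: (sum(M.matrix[p, q] for q in members), p))
            assert rep == medoid
            remaining = [q for q in remaining if q not in set(members)]

    def test_two_separated_blobs_recovered_exactly(self):
        M, energies, labels = _planted_matrix((7, 5), sep=70.0, spread=2.0)
        for cl in (cluster_option_d(M, energies, 7.0),
                   cluster_option_e(M, energies, 7.0),
                   cluster_option_c(M, 7.0)):
            assert len(cl.clusters) == 2
            got_labels = [set(labels[m] for m in c) for c in cl.clusters]
            assert all(len(s) == 1 for s in got_labels)
            assert {s.pop() for s in got_labels} == {0, 1}

    def test_five_cluster_cap(self):
        M, energies, _ = _planted_matrix((3,) * 7, sep=40.0)
        for cl in (cluster_option_d(M, energies, 5.0),
                   cluster_option_e(M, energies, 5.0),
                   cluster_option_c(M, 5.0)):
            assert len(cl.clusters) == 5

    def test_all_within_threshold_is_one_cluster(self):
        M, energies, _ = _planted_matrix((8,), spread=2.0)
        cl = cluster_option_d(M, energies, 50.0)
        assert len(cl.clusters) == 1 and len(cl.clusters[0]) == 8

    def test_option_e_isolated_best_frame_is_singleton(self):
        M, _, _ = _planted_matrix((1, 6), sep=100.0)
        energies = np.arange(7.0)  # frame 0 (the isolated one) is best
        cl = cluster_option_e(M, energies, 5.0)
        assert cl.clusters[0] == [0]
        assert cl.representatives[0] == 0

    def test_option_c_diameter_chain_never_coclusters_far_ends(self):
        M = np.array([
            [0.0, 4.0, 8.0],
            [4.0, 0.0, 4.0],
            [8.0, 4.0, 0.0],
        ])
        cl = cluster_option_c(RMSDMatrix([(0, 0, 0), (0, 0, 1), (0, 0, 2)],
                                         M, True), 5.0)
        for members in cl.clusters:
            assert not {0, 2} <= set(members)

    def test_clusters_disjoint_and_sizes_non_increasing(self):
        M, energies, _ = _planted_matrix((5, 4, 3, 2), sep=30.0, seed=17)
        for cl in (cluster_option_d(M, energies, 5.0), cluster_option_c(M, 5.0)):
            seen = set()
            for members in cl.clusters:
                assert not seen & set(members)
                seen.update(members)
            sizes = [len(c) for c in cl.clusters]
            assert sizes == sorted(sizes, reverse=True)


class TestMCC:
    def test_perfect_prediction_is_one(self):
        assert mcc_basepairs({(0, 5), (1, 4)}, {(0, 5), (1, 4)}, 6) == 1.0

    def test_empty_prediction_is_zero_by_convention(self):
        assert mcc_basepairs({(0, 5), (1, 4)}, set(), 6) == 0.0

    def test_contingency_example(self):
        # TP=1, FP=1, FN=1, TN=12 over the 15 possible pairs of 6 residues
        got = mcc_basepairs({(0, 5), (1, 4)}, {(0, 5), (2, 3)}, 6)
        assert got == pytest.approx(11.0 / 26.0)

    def test_disjoint_prediction_is_nonpositive(self):
        assert mcc_basepairs({(0, 5)}, {(1, 4)}, 6) <= 0.0

    def test_order_of_pair_indices_is_ignored(self):
        assert mcc_basepairs({(5, 0)}, {(0, 5)}, 6) == 1.0

    def test_out_of_range_pair_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            mcc_basepairs({(0, 9)}, set(), 6)


class TestExtractModels:
    def _real_traj(self):
        from cgfold.energy import EnergyModel
        from cgfold.fixtures import FixtureSpec, build_ideal_pair_or_helix
        from cgfold.sampler import SimulationConfig, run_mc

        start, _ = build_ideal_pair_or_helix(
            FixtureSpec(kind="coil", sequence="GGGGAAAACCCC"))
        cfg = SimulationConfig(n_steps=2000, frame_every=100, seed=21)
        return run_mc(start, EnergyModel(), None, cfg)

    def test_best_plus_one_file_per_cluster(self, tmp_path):
        traj = self._real_traj()
        top = select_top_frames(traj, 50.0)
        M = rmsd_matrix(top, superpose=True)
        cl = cluster_option_d(M, [f.energy for f in top], 8.0, max_clusters=3)
        paths = extract_models(top, cl, tmp_path, "pdb")
        assert len(paths) == 1 + len(cl.clusters)
        assert paths[0].name == "best_model.pdb"

    def test_written_representatives_reload_to_their_frames(self, tmp_path):
        traj = self._real_traj()
        top = select_top_frames(traj, 50.0)
        M = rmsd_matrix(top, superpose=True)
        cl = cluster_option_e(M, [f.energy for f in top], 8.0)
        paths = extract_models(top, cl, tmp_path, "pdb")
        best = min(top, key=lambda f: (f.energy, f.key))
        conf = read_structure(paths[0])
        assert np.allclose(conf.coords().ravel(), best.frame.coordinates,
                           atol=1e-3)

    def test_reanalysis_reuses_stored_trajectory_unchanged(self, tmp_path):
        traj = self._real_traj()
        p = tmp_path / "t.traj"
        write_trajectory(traj, p)
        before = p.read_bytes()
        for thr in (4.0, 8.0):
            loaded = read_trajectory(p)
            top = select_top_frames(loaded, 50.0)
            M = rmsd_matrix(top, superpose=True)
            cluster_option_d(M, [f.energy for f in top], thr)
        assert p.read_bytes() == before
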