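import numpy as np
import pytest

from _oracles import brute_cpm_optimum, rand_index
from calyxpath import path_clustering as pc
from calyxpath import synthetic
from calyxpath.dctmd import WorkEnsemble
from calyxpath.traj_io import Trajectory


def random_similarity(seed, n=None):
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(4, 9))
    a = rng.random((n, n))
    s = (a + a.T) / 2.0
    np.fill_diagonal(s, 1.0)
    return pc.SimilarityMatrix(ids=[str(i) for i in range(n)], s=s)


class TestContactFeatures:
    def test_single_contact_residue(self, binding_scenario):
        # ligand parked in the cavity: only nearby residues are features
        spec = synthetic.BindingScenarioSpec(
            schedule=[("e_site_closed", 10.0)], distance_noise=0.01, seed=1
        )
        traj, _, _ = synthetic.gen_binding_trajectory(spec)
        feats = pc.contact_features(traj)
        assert 100 in feats.feature_index  # the cavity cradle
        col = feats.feature_index.index(100)
        assert feats.matrix[:, col].max() < 4.5

    def test_two_path_batch_features_differ_on_planted_residues(self):
        batch, labels = synthetic.gen_path_batch(
            n_per_path=(5, 5),
            fingerprints=[[10, 11], [90, 91]],
            noise_sd=0.1,
            seed=0,
        )
        batch = pc.contact_features_batch(batch)
        assert batch[0].feature_index == [10, 11, 90, 91]
        a = np.mean([f.matrix.mean(axis=0) for f, l in
                     zip(batch, labels) if l == 0], axis=0)
        b = np.mean([f.matrix.mean(axis=0) for f, l in
                     zip(batch, labels) if l == 1], axis=0)
        assert a[0] < 6.0 < b[0]  # path-0 residues close only for path 0
        assert b[2] < 6.0 < a[2]

    def test_zero_cutoff_rejected(self, binding_scenario):
        _, traj, _, _ = binding_scenario
        with pytest.raises(ValueError, match="cutoff"):
            pc.contact_features(traj, cutoff=0.0)


class TestPcaProject:
    def make_features(self, mats):
        return [
            pc.ContactFeatures(
                trajectory_id=str(i), matrix=m,
                feature_index=list(range(mats[0].shape[1])),
            )
            for i, m in enumerate(mats)
        ]

    def test_planar_data_has_two_informative_components(self):
        rng = np.random.default_rng(0)
        basis = rng.random((2, 6))
        mats = [rng.random((40, 2)) @ basis + 5.0 for _ in range(3)]
        _, evr = pc.pca_project(self.make_features(mats), n_components=4)
        assert evr[2:].sum() < 1e-10

    def test_planted_separation_on_pc1(self):
        batch, labels = synthetic.gen_path_batch(
            n_per_path=(10, 10), noise_sd=0.1, seed=1
        )
        batch = pc.contact_features_batch(batch)
        projs, _ = pc.pca_project(batch)
        means = np.array([p[:, 0].mean() for p in projs])
        within_sd = np.mean([p[:, 0].std() for p in projs])
        gap = abs(means[labels == 0].mean() - means[labels == 1].mean())
        assert gap > 5 * within_sd

    def test_frame_duplication_invariance(self):
        rng = np.random.default_rng(2)
        mats = [rng.random((20, 5)) for _ in range(2)]
        projs, evr = pc.pca_project(self.make_features(mats))
        doubled = [np.vstack([m, m]) for m in mats]
        projs2, evr2 = pc.pca_project(self.make_features(doubled))
        np.testing.assert_allclose(evr, evr2, atol=1e-10)
        np.testing.assert_allclose(projs2[0][:20], projs[0], atol=1e-8)

    def test_component_reduction_when_rank_deficient(self):
        rng = np.random.default_rng(3)
        mats = [rng.random((10, 2)) for _ in range(2)]
        projs, evr = pc.pca_project(self.make_features(mats), n_components=4)
        assert projs[0].shape[1] == 2


class TestTrajectorySimilarity:
    def test_identical_trajectories_similarity_one(self):
        p = np.random.default_rng(0).random((15, 4))
        sim = pc.trajectory_similarity([p, p.copy(), p + 3.0])
        assert sim.s[0, 1] == pytest.approx(1.0)

    def test_point_trajectories_closed_form(self):
        # two point-like trajectories at distance D*, sigma = D* -> e^-1
        a = np.zeros((5, 4))
        b = np.zeros((5, 4))
        b[:, 0] = 2.0
        sim = pc.trajectory_similarity([a, b], radius_quantile=0.5)
        assert sim.s[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_planted_paths_within_exceeds_between(self):
        batch, labels = synthetic.gen_path_batch(
            n_per_path=(10, 10), noise_sd=0.3, seed=2
        )
        batch = pc.contact_features_batch(batch)
        projs, _ = pc.pca_project(batch)
        sim = pc.trajectory_similarity(projs)
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(len(labels), k=1)
        within = sim.s[iu][same[iu]].mean()
        between = sim.s[iu][~same[iu]].mean()
        assert within > between

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            pc.trajectory_similarity([np.zeros((0, 4)), np.zeros((3, 4))])


class TestLeidenCpm:
    def test_two_block_matrix_exact(self):
        s = np.full((8, 8), 0.1)
        s[:4, :4] = 0.9
        s[4:, 4:] = 0.9
        np.fill_diagonal(s, 1.0)
        sim = pc.SimilarityMatrix(ids=[str(i) for i in range(8)], s=s)
        part = pc.leiden_cpm(sim, gamma=0.5, seed=0)
        assert part.n_communities == 2
        assert len(set(part.labels[:4])) == 1 and len(set(part.labels[4:])) == 1
        best_q, _ = brute_cpm_optimum(s, 0.5)
        assert part.quality == pytest.approx(best_q, abs=1e-9)

    def test_gamma_zero_single_community(self):
        sim = random_similarity(1)
        part = pc.leiden_cpm(sim, gamma=0.0, seed=0)
        assert part.n_communities == 1

    def test_gamma_above_max_all_singletons(self):
        sim = random_similarity(2)
        part = pc.leiden_cpm(sim, gamma=1.01, seed=0)
        assert part.n_communities == len(sim.ids)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_optimum(self, seed):
        sim = random_similarity(seed)
        part = pc.leiden_cpm(sim, gamma="median", seed=seed)
        best_q, _ = brute_cpm_optimum(sim.s, part.gamma)
        assert part.quality == pytest.approx(best_q, abs=1e-9)

    def test_quality_matches_objective_recomputation(self):
        sim = random_similarity(4)
        part = pc.leiden_cpm(sim, gamma="median", seed=0)
        assert part.quality == pytest.approx(
            pc.cpm_quality(sim.s, part.labels, part.gamma), abs=1e-12
        )

    def test_permutation_equivariance(self):
        sim = random_similarity(5, n=8)
        part = pc.leiden_cpm(sim, gamma="median", seed=0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(8)
        sim_p = pc.SimilarityMatrix(
            ids=[sim.ids[i] for i in perm], s=sim.s[np.ix_(perm, perm)]
        )
        part_p = pc.leiden_cpm(sim_p, gamma="median", seed=0)
        assert rand_index(part.labels[perm], part_p.labels) == 1.0

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            pc.leiden_cpm(random_similarity(6), gamma=-0.1)


class TestFullChain:
    def test_planted_two_path_recovery(self):
        batch, labels = synthetic.gen_path_batch(
            n_per_path=(20, 10), noise_sd=0.5, seed=3
        )
        batch = pc.contact_features_batch(batch)
        projs, _ = pc.pca_project(batch)
        sim = pc.trajectory_similarity(
            projs, ids=[f.trajectory_id for f in batch]
        )
        part = pc.leiden_cpm(sim, gamma="median", seed=0)
        assert rand_index(labels, part.labels) == 1.0
        assert part.community_sizes().max() == 20


class TestLargestClusterWorks:
    def make_partition_and_ensemble(self, sizes):
        ids = [f"t{i}" for i in range(sum(sizes))]
        labels = np.concatenate(
            [np.full(c, i) for i, c in enumerate(sizes)]
        )
        part = pc.CommunityPartition(
            ids=ids, labels=labels, gamma=0.5, quality=0.0
        )
        grid = np.linspace(0.0, 5.0, 11)
        works = np.zeros((len(ids), 11))
        works[:, 1:] = np.random.default_rng(0).random((len(ids), 10))
        works = np.cumsum(works, axis=1)
        ens = WorkEnsemble(grid=grid, works=works, velocity=1.0,
                           temperature=300.0, replica_ids=ids)
        return part, ens

    def test_130_45_25_subset(self):
        part, ens = self.make_partition_and_ensemble([130, 45, 25])
        sub = pc.largest_cluster_works(part, ens)
        assert sub.n_replicas == 130
        assert sub.replica_ids == [f"t{i}" for i in range(130)]

    def test_single_community_identity(self):
        part, ens = self.make_partition_and_ensemble([7])
        sub = pc.largest_cluster_works(part, ens)
        np.testing.assert_array_equal(sub.works, ens.works)

    def test_tie_goes_to_community_zero(self):
        part, ens = self.make_partition_and_ensemble([10, 10])
        sub = pc.largest_cluster_works(part, ens)
        assert sub.replica_ids == [f"t{i}" for i in range(10)]
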