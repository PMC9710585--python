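"""Pose featurization, learned scorers, selection, coclustering, ranking."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from abdock.aa import AA_ORDER
from abdock.pose_scoring import (
    ClusterRecord,
    ClusterScoreRegressor,
    PoseClassifier,
    SelectionConfig,
    cluster_features,
    cocluster,
    irmsd_regression_target,
    pairwise_pose_irmsd,
    pose_features,
    rank_and_evaluate,
    select_top,
)
from abdock.poses import Pose
from abdock.structure import clash_count, contact_map
from abdock.synthetic import DecoySpec, make_decoys


# ------------------------------------------------------------- pose features
class TestPoseFeatures:
    def test_feature_vector_matches_brute_force_recount(self, toy_complex, toy_reference):
        ref = toy_reference
        rng = np.random.default_rng(0)
        paratope_probs = {k: float(p) for k, p in zip(ref.ab.residue_keys, rng.random(ref.ab.n_residues))}
        epitope_probs = {k: float(p) for k, p in zip(ref.ag.residue_keys, rng.random(ref.ag.n_residues))}
        pose = make_decoys(ref, DecoySpec(n_poses=1, true_fraction=1.0, seed=2))[0]
        posed = ref.ab.transformed(pose.rotation, pose.translation)
        feats = pose_features(posed, ref.ag, paratope_probs, epitope_probs)
        assert feats.shape == (47,)
        # independent recount
        cm = contact_map(posed, ref.ag, cutoff=5.0)
        assert feats[40] == clash_count(posed, ref.ag, 2.5)
        for mol, contacts, block in (
            (posed, cm.ab_residues, feats[:20]),
            (ref.ag, cm.ag_residues, feats[20:40]),
        ):
            n_c = len(contacts)
            total_asa = mol.asa.sum()
            for j, aa in enumerate(AA_ORDER):
                obs = sum(1 for k in contacts if mol.sequence[mol.residue_index(k)] == aa)
                exp = n_c * sum(
                    mol.asa[i] for i, a in enumerate(mol.sequence) if a == aa
                ) / total_asa
                assert block[j] == pytest.approx(obs / exp if exp > 0 else 0.0)
        # joint frequencies, antigen side then antibody side
        n_ag = len(cm.ag_residues)
        c_e = sum(1 for k in ref.ag.residue_keys if k in cm.ag_residues and epitope_probs[k] >= 0.5)
        c_ne = sum(1 for k in ref.ag.residue_keys if k in cm.ag_residues and epitope_probs[k] < 0.5)
        nc_e = sum(1 for k in ref.ag.residue_keys if k not in cm.ag_residues and epitope_probs[k] >= 0.5)
        assert np.allclose(feats[41:44], np.array([c_e, c_ne, nc_e]) / n_ag)

    def test_degenerate_pose_all_zero(self, toy_reference):
        ref = toy_reference
        far = ref.ab.transformed(np.eye(3), np.array([500.0, 0, 0]))
        feats = pose_features(far, ref.ag, {}, {})
        assert np.all(feats == 0.0)

    def test_rotation_invariance(self, toy_reference):
        """Rigidly moving the whole posed complex leaves the features unchanged."""
        ref = toy_reference
        rng = np.random.default_rng(3)
        paratope_probs = {k: 0.6 for k in ref.ab.residue_keys}
        epitope_probs = {k: 0.4 for k in ref.ag.residue_keys}
        f1 = pose_features(ref.ab, ref.ag, paratope_probs, epitope_probs)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(size=3) * 10
        f2 = pose_features(
            ref.ab.transformed(R, t), ref.ag.transformed(R, t),
            paratope_probs, epitope_probs,
        )
        assert np.allclose(f1, f2, atol=1e-6)


# ---------------------------------------------------------------- classifier
def _planted_pose_table(n, rng):
    """Features obeying 'True iff clashes < 5 and ag contact-epitope > 0.6'."""
    X = np.zeros((n, 47))
    X[:, :40] = rng.gamma(2.0, 0.5, size=(n, 40))
    X[:, 40] = rng.integers(0, 10, size=n)
    X[:, 41] = rng.random(n)
    X[:, 42:47] = rng.random((n, 5)) * 0.3
    y = ((X[:, 40] < 5) & (X[:, 41] > 0.6)).astype(int)
    flip = rng.random(n) < 0.02  # small label noise
    y[flip] = 1 - y[flip]
    return X, y


class TestPoseClassifier:
    def test_recovers_planted_rule(self):
        rng = np.random.default_rng(0)
        X, y = _planted_pose_table(3000, rng)
        clf = PoseClassifier(random_state=1).fit(X[:2000], y[:2000])
        from abdock.site_predictors import evaluate_binary

        auc = evaluate_binary(clf.score_poses(X[2000:]), y[2000:])["roc_auc"]
        assert auc >= 0.95

    def test_shuffled_labels_near_chance(self):
        from abdock.site_predictors import evaluate_binary

        rng = np.random.default_rng(1)
        X, _ = _planted_pose_table(2400, rng)
        aucs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            y = r.integers(0, 2, size=len(X))
            clf = PoseClassifier(random_state=seed).fit(X[:1600], y[:1600])
            aucs.append(evaluate_binary(clf.score_poses(X[1600:]), y[1600:])["roc_auc"])
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X, y = _planted_pose_table(1200, rng)
        s1 = PoseClassifier(random_state=7).fit(X, y).score_poses(X)
        s2 = PoseClassifier(random_state=7).fit(X, y).score_poses(X)
        assert np.array_equal(s1, s2)

    def test_single_class_raises(self):
        X = np.zeros((10, 47))
        with pytest.raises(ValueError, match="both"):
            PoseClassifier().fit(X, np.zeros(10, dtype=int))

    def test_downsampling_cap(self):
        rng = np.random.default_rng(3)
        X, y = _planted_pose_table(1000, rng)
        clf = PoseClassifier(downsample=200, random_state=0).fit(X, y)
        assert clf.model_ is not None  # trains on the 200-row subsample


# ----------------------------------------------------------------- selection
class TestSelectTop:
    def _pool(self, n, offset=0.0):
        return [(i, offset - i) for i in range(n)]  # descending scores

    def test_default_split_9000_1000(self):
        cfg = SelectionConfig(n_total=10_000, f_piper=0.9)
        out = select_top(self._pool(20_000), self._pool(5_000), cfg)
        assert len(out) == 10_000
        assert out[:9000] == list(range(9000))

    def test_piper_only(self):
        cfg = SelectionConfig(n_total=100, f_piper=1.0)
        out = select_top(self._pool(500), self._pool(500), cfg)
        assert len(out) == 100

    def test_shortage_takes_all_without_backfill(self):
        cfg = SelectionConfig(n_total=10_000, f_piper=0.9)
        out = select_top(self._pool(100), self._pool(5000), cfg)
        assert len(out) == 100 + 1000

    def test_monotone_in_f_piper(self):
        piper, hexp = self._pool(300), self._pool(300)
        counts = []
        for f in (0.0, 0.3, 0.6, 1.0):
            cfg = SelectionConfig(n_total=200, f_piper=f)
            out = select_top(piper, hexp, cfg)
            counts.append(int(round(200 * f)))
            assert len(out) <= 200
        assert counts == sorted(counts)


# -------------------------------------------------------------- coclustering
def _brute_force_cocluster(coords, cutoff):
    """Independent greedy re-implementation recounting neighbours each round."""
    n = len(coords)
    a = np.asarray(coords, dtype=float).reshape(n, -1)
    natoms = a.shape[1] // 3
    alive = set(range(n))
    clusters = []
    while alive:
        best, best_count = None, -1
        for i in sorted(alive):
            count = sum(
                1
                for j in alive
                if j != i
                and np.sqrt(np.sum((a[i] - a[j]) ** 2) / natoms) <= cutoff
            )
            if count > best_count:
                best, best_count = i, count
        members = sorted(
            {best}
            | {
                j
                for j in alive
                if np.sqrt(np.sum((a[best] - a[j]) ** 2) / natoms) <= cutoff
            }
        )
        clusters.append((best, members))
        alive -= set(members)
    return clusters


class TestCocluster:
    def test_three_near_one_far(self):
        base = np.zeros((4, 3))
        coords = np.stack([
            base, base + [1.0, 0, 0], base + [0, 1.0, 0], base + [100.0, 0, 0],
        ])
        clusters = cocluster(coords, cutoff=10.0)
        sizes = sorted(c.size for c in clusters)
        assert sizes == [1, 3]

    def test_identical_poses_tie_breaks_to_lowest_id(self):
        coords = np.zeros((5, 4, 3))
        clusters = cocluster(coords, cutoff=10.0)
        assert len(clusters) == 1
        assert clusters[0].representative == 0
        assert clusters[0].members == [0, 1, 2, 3, 4]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed, toy_reference):
        poses = make_decoys(
            toy_reference, DecoySpec(n_poses=60, true_fraction=0.3, seed=seed)
        )
        idx = [toy_reference.ab.residue_index(k) for k in sorted(toy_reference.interface_ab)]
        atom_idx = toy_reference.ab.backbone_atom_indices(idx)
        B = np.asarray(toy_reference.ab.coords[atom_idx], dtype=float)
        coords = np.asarray([B @ p.rotation.T + p.translation for p in poses])
        clusters = cocluster(coords, cutoff=10.0)
        oracle = _brute_force_cocluster(coords, 10.0)
        assert [(c.representative, c.members) for c in clusters] == oracle

    def test_partitions_input(self, toy_reference):
        poses = make_decoys(toy_reference, DecoySpec(n_poses=40, seed=1))
        idx = [toy_reference.ab.residue_index(k) for k in sorted(toy_reference.interface_ab)]
        atom_idx = toy_reference.ab.backbone_atom_indices(idx)
        B = np.asarray(toy_reference.ab.coords[atom_idx], dtype=float)
        coords = np.asarray([B @ p.rotation.T + p.translation for p in poses])
        clusters = cocluster(coords, cutoff=10.0)
        all_members = [m for c in clusters for m in c.members]
        assert sorted(all_members) == list(range(40))  # disjoint and complete
        D = pairwise_pose_irmsd(coords)
        for c in clusters:
            for m in c.members:
                assert D[c.representative, m] <= 10.0 + 1e-9

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            cocluster(np.zeros((0, 3, 3)))


# ----------------------------------------------------- cluster features/score
class TestClusterFeatures:
    def test_pure_piper_cluster(self):
        c = ClusterRecord(representative=2, members=list(range(10)))
        f = cluster_features(
            c, engine_scores=np.arange(10.0), clashes=np.zeros(10),
            raw_energies=np.full(10, -7.0), engines=["piper"] * 10,
        )
        assert f[0] == 2.0 and f[2] == -7.0
        assert f[3] == 1.0 and f[4] == 10.0

    def test_mixed_engines_fraction(self):
        c = ClusterRecord(representative=0, members=[0, 1, 2, 3])
        f = cluster_features(
            c, np.ones(4), np.ones(4), np.ones(4), ["piper", "piper", "piper", "hex"]
        )
        assert f[3] == 0.75


class TestClusterScoreRegressor:
    def test_regression_target_formula(self):
        assert irmsd_regression_target([2.0])[0] == pytest.approx(0.25)
        assert irmsd_regression_target([10.0])[0] == pytest.approx(0.01)
        # floor keeps the target bounded
        assert irmsd_regression_target([0.0])[0] == pytest.approx(4.0)

    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(0)
        irmsd = rng.uniform(1.0, 40.0, size=600)
        X = np.zeros((600, 5))
        X[:, 0] = (1.0 / irmsd**2) * (1.0 + rng.normal(0, 0.05, 600))
        X[:, 1:] = rng.random((600, 4))
        reg = ClusterScoreRegressor(random_state=1).fit(X[:400], irmsd[:400])
        pred = reg.predict(X[400:])
        rho = spearmanr(pred, 1.0 / np.clip(irmsd[400:], 0.5, None) ** 2).statistic
        assert rho >= 0.8

    def test_permuted_targets_uninformative(self):
        rng = np.random.default_rng(1)
        irmsd = rng.uniform(1.0, 40.0, size=600)
        X = np.zeros((600, 5))
        X[:, 0] = 1.0 / irmsd**2
        X[:, 1:] = rng.random((600, 4))
        perm = rng.permutation(irmsd)
        reg = ClusterScoreRegressor(random_state=2).fit(X[:400], perm[:400])
        rho = spearmanr(reg.predict(X[400:]), 1.0 / np.clip(perm[400:], 0.5, None) ** 2).statistic
        assert abs(rho) <= 0.3


# ------------------------------------------------------------------- ranking
class TestRankAndEvaluate:
    def _clusters(self, scores, sizes=None):
        sizes = sizes or [1] * len(scores)
        return [
            ClusterRecord(representative=i, members=list(range(s)), final_score=sc)
            for i, (sc, s) in enumerate(zip(scores, sizes))
        ]

    def test_true_rank_position(self):
        clusters = self._clusters([3.0, 2.0, 1.0])
        labels = {0: False, 1: True, 2: False}
        assert rank_and_evaluate(clusters, labels) == {"true_rank": 2, "coverage": True}

    def test_no_true_representative(self):
        clusters = self._clusters([3.0, 2.0])
        out = rank_and_evaluate(clusters, {0: False, 1: False})
        assert out == {"true_rank": None, "coverage": False}

    def test_top_pose_true_is_rank_one(self):
        clusters = self._clusters([5.0, 1.0])
        assert rank_and_evaluate(clusters, {0: True, 1: True})["true_rank"] == 1

    def test_tie_breaks_larger_cluster_first(self):
        clusters = self._clusters([1.0, 1.0], sizes=[1, 5])
        labels = {0: False, 1: True}
        assert rank_and_evaluate(clusters, labels)["true_rank"] == 1
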