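"""Pose featurization, learned scoring, coclustering and final ranking.

Stages, in pipeline order:

1. Each docked pose gets a rotation-invariant 47-term feature vector:
   observed/expected contact ratios for the 20 amino-acid types on each
   molecule (expected contacts proportional to surface-area composition),
   the interatomic clash count, and six joint frequencies relating
   observed contacts to the predicted paratope/epitope at a 0.5 cutoff
   (the dominant noncontact-and-nonsite term is dropped on each side).
2. Per-engine gradient-boosted classifiers (:class:`PoseClassifier`) are
   trained on True/False pose labels with minority up-weighting and a
   10 000-pose training cap.
3. The engine-scored pools are merged: top ``n_total * f_piper`` global
   poses plus the remainder from the local engine.
4. Merged poses are coclustered progressively by pairwise IRMSD: the pose
   with the most unassigned neighbours within the cutoff becomes the next
   cluster representative.
5. Cluster representatives get a 5-term feature vector and a final score
   from :class:`ClusterScoreRegressor`, a gradient-boosted regression
   against 1/IRMSD^2, and are ranked; the True Rank is the 1-based rank of
   the first True representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from xgboost import XGBClassifier, XGBRegressor

from .aa import AA_ORDER
from .structure import Structure, clash_count, contact_map

IRMSD_FLOOR = 0.5  # A; caps the 1/IRMSD^2 regression target at 4


# ------------------------------------------------------------- pose features
def pose_feature_names() -> list[str]:
    names = [f"ab_ratio_{a}" for a in AA_ORDER]
    names += [f"ag_ratio_{a}" for a in AA_ORDER]
    names += ["clashes"]
    names += [
        "ag_contact_epitope", "ag_contact_nonepitope", "ag_noncontact_epitope",
        "ab_contact_paratope", "ab_contact_nonparatope", "ab_noncontact_paratope",
    ]
    return names


def _contact_ratios(molecule: Structure, contact_keys: set) -> np.ndarray:
    """Observed/expected contact counts per amino-acid type.

    Expected contacts for a type are proportional to that type's share of
    the molecule's solvent-accessible surface area.
    """
    if molecule.asa is None:
        raise ValueError("compute_asa required before pose featurization")
    total_asa = float(molecule.asa.sum())
    n_contacts = len(contact_keys)
    ratios = np.zeros(20)
    if n_contacts == 0 or total_asa <= 0:
        return ratios
    asa_by_type = {a: 0.0 for a in AA_ORDER}
    for i, a in enumerate(molecule.sequence):
        if a in asa_by_type:
            asa_by_type[a] += molecule.asa[i]
    observed = {a: 0 for a in AA_ORDER}
    for k in contact_keys:
        a = molecule.sequence[molecule.residue_index(k)]
        if a in observed:
            observed[a] += 1
    for j, a in enumerate(AA_ORDER):
        expected = n_contacts * asa_by_type[a] / total_asa
        ratios[j] = observed[a] / expected if expected > 0 else 0.0
    return ratios


def _joint_frequencies(keys, contact_keys: set, site_probs: dict, threshold: float):
    n_contacts = len(contact_keys)
    if n_contacts == 0:
        return np.zeros(3)
    c_s = c_ns = nc_s = 0
    for k in keys:
        contact = k in contact_keys
        site = site_probs.get(k, 0.0) >= threshold
        if contact and site:
            c_s += 1
        elif contact and not site:
            c_ns += 1
        elif site:
            nc_s += 1
    return np.array([c_s, c_ns, nc_s], dtype=float) / n_contacts


def pose_features(
    posed_ab: Structure,
    ag: Structure,
    paratope_probs: dict,
    epitope_probs: dict,
    threshold: float = 0.5,
    contact_cutoff: float = 5.0,
    clash_cutoff: float = 2.5,
) -> np.ndarray:
    """47-term rotation-invariant feature vector for one posed complex."""
    cm = contact_map(posed_ab, ag, cutoff=contact_cutoff)
    ab_contacts, ag_contacts = cm.ab_residues, cm.ag_residues
    return np.concatenate(
        [
            _contact_ratios(posed_ab, ab_contacts),
            _contact_ratios(ag, ag_contacts),
            [float(clash_count(posed_ab, ag, clash_cutoff))],
            _joint_frequencies(ag.residue_keys, ag_contacts, epitope_probs, threshold),
            _joint_frequencies(posed_ab.residue_keys, ab_contacts, paratope_probs, threshold),
        ]
    )


# --------------------------------------------------------- learned pose score
class PoseClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted True/False pose classifier (one per engine).

    Training poses are randomly downsampled to ``downsample`` rows and the
    minority (True) class is up-weighted by the False/True count ratio.
    """

    def __init__(
        self,
        n_estimators: int = 300,
        max_depth: int = 4,
        learning_rate: float = 0.1,
        downsample: int = 10_000,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.downsample = downsample
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int).ravel()
        rng = np.random.default_rng(self.random_state)
        if len(y) > self.downsample:
            idx = rng.choice(len(y), size=self.downsample, replace=False)
            X, y = X[idx], y[idx]
        n_pos, n_neg = int(y.sum()), int((1 - y).sum())
        if n_pos == 0 or n_neg == 0:
            raise ValueError("both True and False poses required for training")
        self.model_ = XGBClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            scale_pos_weight=n_neg / n_pos,
            tree_method="hist",
            n_jobs=1,
            random_state=self.random_state,
            eval_metric="logloss",
        )
        self.model_.fit(X, y)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score_poses(self, X) -> np.ndarray:
        """Probability-like score; higher means more True-like."""
        return self.predict_proba(X)[:, 1]


# -------------------------------------------------------------- selection
@dataclass
class SelectionConfig:
    n_total: int = 10_000
    f_piper: float = 0.9
    cluster_cutoff: float = 10.0
    downsample_training: int = 10_000

    def __post_init__(self):
        if not (0.0 <= self.f_piper <= 1.0):
            raise ValueError("f_piper must be in [0, 1]")


def select_top(piper_scored, hex_scored, cfg: SelectionConfig) -> list:
    """Merge the per-engine pools: top ``n_total*f_piper`` global (Piper-style)
    poses plus the remaining budget of local (Hex-style) poses.

    Each input is a sequence of ``(pose_index, score)``; an engine short of
    its quota contributes everything it has (no backfill).
    """
    quota_piper = int(round(cfg.n_total * cfg.f_piper))
    quota_hex = cfg.n_total - quota_piper
    top_p = sorted(piper_scored, key=lambda t: -t[1])[:quota_piper]
    top_h = sorted(hex_scored, key=lambda t: -t[1])[:quota_hex]
    return [i for i, _ in top_p] + [i for i, _ in top_h]


# -------------------------------------------------------------- coclustering
@dataclass
class ClusterRecord:
    representative: int
    members: list
    features: np.ndarray | None = None
    final_score: float | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def pairwise_pose_irmsd(interface_coords: np.ndarray) -> np.ndarray:
    """Dense pairwise IRMSD matrix from per-pose interface backbone coords.

    ``interface_coords`` has shape (n_poses, n_atoms, 3); all poses share
    the same atom ordering (same antibody, antigen frame fixed), so the
    pairwise RMSD is the flat euclidean distance scaled by 1/sqrt(n_atoms).
    """
    arr = np.asarray(interface_coords, dtype=float)
    n, a, _ = arr.shape
    flat = arr.reshape(n, a * 3)
    return squareform(pdist(flat) / np.sqrt(a))


def cocluster(interface_coords: np.ndarray, cutoff: float = 10.0) -> list[ClusterRecord]:
    """Progressive greedy IRMSD clustering.

    Repeatedly promotes the unassigned pose with the most unassigned
    neighbours within ``cutoff`` (ties -> lowest pose index) to cluster
    representative, assigns it together with those neighbours, and repeats
    until every pose is clustered.  Singletons are allowed.
    """
    n = len(interface_coords)
    if n == 0:
        raise ValueError("empty pose list")
    D = pairwise_pose_irmsd(interface_coords)
    neighbor = D <= cutoff
    np.fill_diagonal(neighbor, False)
    alive = np.ones(n, dtype=bool)
    # unassigned-neighbour counts, maintained incrementally as clusters are
    # removed (equivalent to recounting each round)
    counts = neighbor.sum(axis=1).astype(np.int64)
    clusters: list[ClusterRecord] = []
    n_left = n
    while n_left > 0:
        masked = np.where(alive, counts, -1)
        rep = int(np.argmax(masked))  # argmax takes the lowest index on ties
        members = [rep] + [int(j) for j in np.nonzero(neighbor[rep] & alive)[0] if j != rep]
        clusters.append(ClusterRecord(representative=rep, members=sorted(members)))
        alive[members] = False
        counts -= neighbor[:, members].sum(axis=1)
        n_left -= len(members)
    return clusters


def cluster_features(
    cluster: ClusterRecord,
    engine_scores: np.ndarray,
    clashes: np.ndarray,
    raw_energies: np.ndarray,
    engines: list,
) -> np.ndarray:
    """5-term cluster feature vector.

    (representative engine score, representative clash count, representative
    raw energy, fraction of global-engine poses among members, cluster size)
    """
    rep = cluster.representative
    piper_fraction = float(np.mean([engines[m] == "piper" for m in cluster.members]))
    return np.array(
        [
            float(engine_scores[rep]),
            float(clashes[rep]),
            float(raw_energies[rep]),
            piper_fraction,
            float(cluster.size),
        ]
    )


CLUSTER_FEATURE_NAMES = ["engine_score", "clashes", "raw_energy", "piper_fraction", "cluster_size"]


# ------------------------------------------------------------ final regressor
def irmsd_regression_target(irmsd_values, floor: float = IRMSD_FLOOR) -> np.ndarray:
    """1/IRMSD^2 target, with IRMSD floored to keep the target bounded."""
    v = np.clip(np.asarray(irmsd_values, dtype=float), floor, None)
    return 1.0 / v**2


class ClusterScoreRegressor(BaseEstimator, RegressorMixin):
    """Gradient-boosted regression of cluster features against 1/IRMSD^2."""

    def __init__(
        self,
        n_estimators: int = 300,
        max_depth: int = 4,
        learning_rate: float = 0.1,
        irmsd_floor: float = IRMSD_FLOOR,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.irmsd_floor = irmsd_floor
        self.random_state = random_state

    def fit(self, X, irmsd_values):
        X = np.asarray(X, dtype=float)
        if len(X) < 2:
            raise ValueError("need at least 2 clusters to fit the final regressor")
        y = irmsd_regression_target(irmsd_values, self.irmsd_floor)
        self.model_ = XGBRegressor(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            tree_method="hist",
            n_jobs=1,
            random_state=self.random_state,
        )
        self.model_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted 1/IRMSD^2; higher means predicted nearer native."""
        return self.model_.predict(np.asarray(X, dtype=float)).astype(float)


# ------------------------------------------------------------------- ranking
def rank_clusters(clusters: list[ClusterRecord]) -> list[ClusterRecord]:
    """Sort by final score descending; ties -> larger cluster, then lower pose id."""
    return sorted(
        clusters,
        key=lambda c: (-(c.final_score if c.final_score is not None else -np.inf),
                       -c.size, c.representative),
    )


def rank_and_evaluate(clusters: list[ClusterRecord], labels: dict) -> dict:
    """True Rank and coverage of a scored, labeled cluster set.

    ``labels`` maps representative pose index -> bool.  Returns
    ``{"true_rank": int | None, "coverage": bool}``; the True Rank is the
    1-based rank of the highest-scoring True representative.
    """
    ordered = rank_clusters(clusters)
    true_rank = None
    for rank, c in enumerate(ordered, start=1):
        if labels.get(c.representative, False):
            true_rank = rank
            break
    return {"true_rank": true_rank, "coverage": true_rank is not None}
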