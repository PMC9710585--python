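"""Pipeline orchestration: features -> site predictions -> patches ->
pose scoring -> coclustering -> docking-informed epitope re-prediction.

Two entry modes share the same stage code:

* fixture mode (``run_fixture_pipeline``): everything — training complexes,
  the query complex and its decoy set — is generated from the config seed,
  the scoring stack is trained on the synthetic training complexes, and the
  query is pushed through every stage;
* file mode (``run_pipeline``): caller supplies structures, CDR table and a
  pose table plus a pre-trained scoring stack.

Each stage writes its artifact (TSV/PDB) into the output directory and the
run ends with a ``summary.json``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    CdrAnnotation,
    ConservationProfile,
    build_feature_matrix,
    fallback_conservation,
)
from .final_epitope import (
    RestraintSet,
    apply_restraints,
    build_final_epitope_features,
    docking_profile,
    representative_contacts,
)
from .patches import build_patches, filter_patches, patches_to_tsv
from .pose_scoring import SelectionConfig, pose_features, rank_and_evaluate
from .poses import TruePoseCriteria, load_pose_table
from .simulation import (
    ScoringStack,
    cluster_and_featurize,
    featurize_decoys,
    fit_final_epitope_ensemble,
    fit_scoring_stack,
    predict_final_epitope,
    predict_site_probs,
    prepared_complex,
    score_decoy_set,
    _child_seeds,
)
from .site_predictors import SiteBindingClassifier, evaluate_binary
from .structure import compute_asa, read_structure
from .synthetic import DecoySpec, ToyComplexSpec, make_decoys


@dataclass
class PipelineConfig:
    """Global thresholds of the pipeline, with their standard defaults."""

    contact_cutoff: float = 5.0
    interface_cutoff: float = 10.0
    window: int = 5
    cdr_flank: int = 2
    patch_radius: float = 20.0
    patch_sep: float = 10.0
    patch_keep_fraction: float = 0.5
    rmsd_true: float = 15.0
    par_true: float = 0.5
    ep_true: float = 0.5
    f_piper: float = 0.9
    n_total: int = 10_000
    cluster_cutoff: float = 10.0
    clash_cutoff: float = 2.5
    n_score_bins: int = 10
    binary_threshold: float = 0.5
    seed: int = 17
    # fixture-mode sizes
    n_train_complexes: int = 2
    n_train_decoys: int = 300
    n_decoys: int = 1000
    true_fraction: float = 0.05

    def __post_init__(self):
        for name in ("contact_cutoff", "patch_radius", "patch_sep", "rmsd_true",
                     "cluster_cutoff", "n_total", "n_score_bins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("par_true", "ep_true", "f_piper", "patch_keep_fraction",
                     "binary_threshold", "true_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Read a flat ``key = value`` config file (one pair per line,
        ``#`` comments allowed)."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, value = (t.strip() for t in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"unknown config key: {key!r}")
            current = getattr(cls(), key)
            kwargs[key] = type(current)(float(value)) if isinstance(current, (int, float)) else value
        return cls(**kwargs)

    def selection(self) -> SelectionConfig:
        return SelectionConfig(
            n_total=self.n_total, f_piper=self.f_piper, cluster_cutoff=self.cluster_cutoff
        )

    def criteria(self) -> TruePoseCriteria:
        return TruePoseCriteria(
            rmsd_true=self.rmsd_true, par_true=self.par_true, ep_true=self.ep_true
        )


def _write_probs(path, probs: dict) -> None:
    pd.DataFrame(
        [{"chain": k[0], "resnum": k[1], "prob": float(p)} for k, p in probs.items()]
    ).to_csv(path, sep="\t", index=False)


def run_fixture_pipeline(
    config: PipelineConfig,
    out_dir,
    restraints: RestraintSet | None = None,
) -> dict:
    """Seeded end-to-end run on generated fixtures; writes all stage files.

    Returns the summary dict (also written to ``summary.json``): pose
    counts per stage, True Rank and coverage of the final cluster set, and
    epitope metrics for the query antigen.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 4)
    log: list[str] = []

    def stage(msg):
        log.append(msg)

    # stage 0: fixtures + scoring stack
    train = [
        prepared_complex(ToyComplexSpec(seed=s))
        for s in _child_seeds(seeds[0], config.n_train_complexes)
    ]
    query = prepared_complex(ToyComplexSpec(seed=seeds[1]))
    query.write_dir(out / "fixture")
    stage(f"fixtures: {len(train)} training complexes + query written")
    stack = fit_scoring_stack(
        train, seeds[2], n_train_decoys=config.n_train_decoys,
        true_fraction=config.true_fraction, selection=config.selection(),
    )

    # stage 1: site predictions
    paratope_probs, epitope_probs = predict_site_probs(
        query, stack.paratope_model, stack.epitope_model
    )
    _write_probs(out / "paratope_probs.tsv", paratope_probs)
    if restraints is not None:
        ca_map = {
            k: query.ag.ca_coords()[i] for i, k in enumerate(query.ag.residue_keys)
        }
        epitope_probs = apply_restraints(epitope_probs, restraints, ca_map)
        stage(f"restraints: {len(restraints.manual)} manual residues applied")
    _write_probs(out / "epitope_probs.tsv", epitope_probs)
    stage(
        f"site predictions: {len(paratope_probs)} paratope rows, "
        f"{len(epitope_probs)} antigen residues"
    )

    # stage 2: patches
    ca = {k: c for k, c in zip(query.ag.residue_keys, query.ag.ca_coords())}
    rsa = {k: r for k, r in zip(query.ag.residue_keys, query.ag.rsa)}
    patches = build_patches(
        epitope_probs, ca, radius=config.patch_radius,
        min_center_sep=config.patch_sep, rsa=rsa,
    )
    retained = filter_patches(patches, keep_fraction=config.patch_keep_fraction)
    patches_to_tsv(retained, out / "patches.tsv")
    stage(f"patches: {len(patches)} built, {len(retained)} retained")

    # stage 3: decoys + per-engine scoring
    ref = query.reference()
    decoys = make_decoys(
        ref, DecoySpec(n_poses=config.n_decoys, true_fraction=config.true_fraction,
                       seed=seeds[3]),
    )
    ds = featurize_decoys(query, ref, decoys, paratope_probs, epitope_probs,
                          crit=config.criteria())
    score_decoy_set(ds, stack.engine_scorers)
    stage(
        f"poses: {len(decoys)} decoys, {int(ds.labels.sum())} True "
        f"({np.mean(ds.labels):.1%})"
    )

    # stage 4: selection + coclustering + final scoring
    clusters, feats, _ = cluster_and_featurize(ds, stack.selection)
    final_scores = stack.regressor.predict(feats)
    for c, s in zip(clusters, final_scores):
        c.final_score = float(s)
    rep_labels = {c.representative: bool(ds.labels[c.representative]) for c in clusters}
    result = rank_and_evaluate(clusters, rep_labels)
    pose_rows = []
    cluster_of = {m: ci for ci, c in enumerate(clusters) for m in c.members}
    for i, p in enumerate(ds.poses):
        pose_rows.append(
            {
                "pose_id": p.pose_id, "engine": p.engine,
                "score": float(ds.engine_scores[i]),
                "cluster_id": cluster_of.get(i, -1),
                "representative": int(any(c.representative == i for c in clusters)),
                "final_score": next(
                    (c.final_score for c in clusters if c.representative == i), np.nan
                ),
                "label": bool(ds.labels[i]), "irmsd": float(ds.irmsd[i]),
                "raw_energy": p.raw_energy,
            }
        )
    pd.DataFrame(pose_rows).to_csv(out / "scored_poses.tsv", sep="\t", index=False)
    stage(
        f"clusters: {len(clusters)} (True reps "
        f"{sum(rep_labels.values())}); true_rank={result['true_rank']}"
    )

    # stage 5: docking-informed epitope re-prediction
    reps = [ds.poses[c.representative] for c in clusters]
    contacts = representative_contacts(ref.ab, ref.ag, reps)
    profile = docking_profile(
        np.array([c.final_score for c in clusters]), contacts, query.ag,
        n_bins=config.n_score_bins,
    )
    fm_final = build_final_epitope_features(
        query.ag, fallback_conservation(query.ag.sequence), profile
    )
    y_ag = query.ag_labels.vector(fm_final.row_keys)
    # the final model is trained on the training complexes' own profiles
    Xf, yf, gf = [], [], []
    for i, tc in enumerate(train):
        from .simulation import scored_docking_profile  # local to avoid cycle

        prof_t = scored_docking_profile(
            tc, stack,
            DecoySpec(n_poses=min(config.n_decoys, 300),
                      true_fraction=max(config.true_fraction, 0.2),
                      seed=seeds[2] + 101 + i),
        )
        fm_t = build_final_epitope_features(
            tc.ag, fallback_conservation(tc.ag.sequence), prof_t
        )
        Xf.append(fm_t.values)
        yf.append(tc.ag_labels.vector(fm_t.row_keys))
        gf += [i] * len(fm_t.row_keys)
    ensemble = fit_final_epitope_ensemble(
        np.vstack(Xf), np.concatenate(yf), np.array(gf), seeds[2] ^ 0xBEEF
    )
    final_probs = predict_final_epitope(ensemble, fm_final.values)
    init_fm = build_feature_matrix(
        query.ag, fallback_conservation(query.ag.sequence), mode="epitope"
    )
    init_probs = stack.epitope_model.predict_proba(init_fm.values)[:, 1]
    pd.DataFrame(
        {
            "chain": [k[0] for k in fm_final.row_keys],
            "resnum": [k[1] for k in fm_final.row_keys],
            "initial_prob": init_probs,
            "final_prob": final_probs,
            "label": y_ag,
        }
    ).to_csv(out / "final_epitope.tsv", sep="\t", index=False)
    epi_metrics = {}
    if len(np.unique(y_ag)) == 2:
        epi_metrics = {
            "initial_epitope_roc_auc": evaluate_binary(init_probs, y_ag)["roc_auc"],
            "final_epitope_roc_auc": evaluate_binary(final_probs, y_ag)["roc_auc"],
        }
    stage("final epitope: re-prediction written")

    summary = {
        "true_rank": result["true_rank"],
        "coverage": result["coverage"],
        "n_clusters": len(clusters),
        "n_poses": len(decoys),
        "n_patches_retained": len(retained),
        "stages": log,
        **epi_metrics,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    ab_pdb,
    ag_pdb,
    cdr_tsv,
    pose_table,
    stack: ScoringStack,
    ab_chains=("H", "L"),
    ag_chains=("A",),
    pssm: ConservationProfile | None = None,
    restraints: RestraintSet | None = None,
) -> dict:
    """Score a supplied pose table with a pre-trained stack.

    The native complex is not required: the antibody's predicted paratope
    substitutes for the reference interface in pairwise pose IRMSD, and no
    True/False labels or ranks are reported.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cdr_tsv is None or not Path(cdr_tsv).exists():
        raise FileNotFoundError("CDR annotation table is required (stage 1)")
    ab = read_structure(ab_pdb, chain_ids=list(ab_chains))
    ag = read_structure(ag_pdb, chain_ids=list(ag_chains))
    compute_asa(ab)
    compute_asa(ag)
    cdrs = CdrAnnotation.from_tsv(cdr_tsv, flank=config.cdr_flank)
    prof_ab = fallback_conservation(ab.sequence)
    prof_ag = pssm if pssm is not None else fallback_conservation(ag.sequence)

    fm_p = build_feature_matrix(ab, prof_ab, cdrs=cdrs, mode="paratope")
    fm_e = build_feature_matrix(ag, prof_ag, mode="epitope")
    paratope_probs = dict(zip(fm_p.row_keys, stack.paratope_model.predict_proba(fm_p.values)[:, 1]))
    epitope_probs = dict(zip(fm_e.row_keys, stack.epitope_model.predict_proba(fm_e.values)[:, 1]))
    _write_probs(out / "paratope_probs.tsv", paratope_probs)
    if restraints is not None:
        ca_map = {k: c for k, c in zip(ag.residue_keys, ag.ca_coords())}
        epitope_probs = apply_restraints(epitope_probs, restraints, ca_map)
    _write_probs(out / "epitope_probs.tsv", epitope_probs)

    ca = {k: c for k, c in zip(ag.residue_keys, ag.ca_coords())}
    rsa = {k: r for k, r in zip(ag.residue_keys, ag.rsa)}
    retained = filter_patches(
        build_patches(epitope_probs, ca, radius=config.patch_radius,
                      min_center_sep=config.patch_sep, rsa=rsa),
        keep_fraction=config.patch_keep_fraction,
    )
    patches_to_tsv(retained, out / "patches.tsv")

    poses = load_pose_table(pose_table)
    feats = np.asarray(
        [
            pose_features(
                ab.transformed(p.rotation, p.translation), ag,
                paratope_probs, epitope_probs,
                threshold=config.binary_threshold,
                contact_cutoff=config.contact_cutoff,
                clash_cutoff=config.clash_cutoff,
            )
            for p in poses
        ]
    )
    scores = np.zeros(len(poses))
    for engine in ("piper", "hex"):
        mask = np.array([p.engine == engine for p in poses])
        model = stack.engine_scorers.get(engine)
        if mask.any() and model is not None:
            scores[mask] = model.score_poses(feats[mask])
        elif mask.any():
            scores[mask] = -np.array([p.raw_energy for p in poses])[mask]
    pd.DataFrame(
        {
            "pose_id": [p.pose_id for p in poses],
            "engine": [p.engine for p in poses],
            "score": scores,
        }
    ).to_csv(out / "scored_poses.tsv", sep="\t", index=False)
    summary = {"n_poses": len(poses), "n_patches_retained": len(retained)}
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
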