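"""Docked-pose representation, reference-complex construction and labeling.

A pose is a rigid transform of the antibody relative to the antigen held
fixed in its input frame; the identity pose leaves the antibody where the
reference complex put it.  Poses arrive as a plain TSV "pose table" (one
row per pose: engine tag, rotation as a quaternion or 3x3 matrix, the
translation, the engine's raw energy and an optional patch id), which is
the neutral interchange format for any rigid-body docking engine.

The reference complex is the ground truth for labeling: antibody and
antigen models are superposed onto the native complex via their paratope
and epitope C-alpha atoms respectively, so a pose can score a zero IRMSD
even when the models themselves are imperfect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure import (
    Structure,
    contact_map,
    interface_residues,
    rmsd,
    superpose,
)

ORTHO_TOL = 1e-4


@dataclass
class Pose:
    """Rigid transform of the antibody with bookkeeping fields."""

    rotation: np.ndarray
    translation: np.ndarray
    engine: str = "synthetic"
    raw_energy: float = float("nan")
    patch_id: int = -1
    pose_id: int = -1
    score: float | None = None
    label: bool | None = None
    irmsd_to_ref: float | None = None

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        err = np.abs(R @ R.T - np.eye(3)).max()
        if err > ORTHO_TOL:
            raise ValueError(f"rotation not orthonormal (error {err:.2e})")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (det = -1)")
        # re-orthonormalise small drift
        U, _, Vt = np.linalg.svd(R)
        self.rotation = U @ Vt
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def invert(self) -> "Pose":
        Rinv = self.rotation.T
        return Pose(rotation=Rinv, translation=-Rinv @ self.translation,
                    engine=self.engine, pose_id=self.pose_id)

    @property
    def quaternion(self) -> np.ndarray:
        """Scalar-first unit quaternion (qw, qx, qy, qz)."""
        q = Rotation.from_matrix(self.rotation).as_quat()  # x, y, z, w
        return np.array([q[3], q[0], q[1], q[2]])


# -------------------------------------------------------------- pose tables
_QUAT_COLS = ["qw", "qx", "qy", "qz"]
_MAT_COLS = [f"r{i}{j}" for i in range(3) for j in range(3)]


def save_pose_table(poses: list[Pose], path) -> None:
    rows = []
    for p in poses:
        q = p.quaternion
        rows.append(
            {
                "pose_id": p.pose_id,
                "engine": p.engine,
                "qw": q[0], "qx": q[1], "qy": q[2], "qz": q[3],
                "tx": p.translation[0], "ty": p.translation[1], "tz": p.translation[2],
                "raw_energy": p.raw_energy,
                "patch_id": p.patch_id,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.9g")


def load_pose_table(path) -> list[Pose]:
    """Read a pose table TSV; accepts quaternion or rotation-matrix dialects.

    Raises
    ------
    ValueError
        On malformed rows, non-unit/improper rotations beyond tolerance, or
        a missing rotation column set.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"engine", "tx", "ty", "tz", "raw_energy"}
    if not required.issubset(df.columns):
        raise ValueError(f"pose table missing columns {sorted(required - set(df.columns))}")
    has_quat = set(_QUAT_COLS).issubset(df.columns)
    has_mat = set(_MAT_COLS).issubset(df.columns)
    if not (has_quat or has_mat):
        raise ValueError("pose table needs qw..qz or r00..r22 rotation columns")
    poses = []
    for i, row in df.iterrows():
        if has_quat:
            q = row[_QUAT_COLS].to_numpy(dtype=float)
            norm = np.linalg.norm(q)
            if not np.isfinite(norm) or abs(norm - 1.0) > 1e-2:
                raise ValueError(f"row {i}: quaternion norm {norm:.4f} far from 1")
            R = Rotation.from_quat(q / norm, scalar_first=True).as_matrix()
        else:
            R = row[_MAT_COLS].to_numpy(dtype=float).reshape(3, 3)
        poses.append(
            Pose(
                rotation=R,
                translation=row[["tx", "ty", "tz"]].to_numpy(dtype=float),
                engine=str(row["engine"]),
                raw_energy=float(row["raw_energy"]),
                patch_id=int(row["patch_id"]) if "patch_id" in df.columns and pd.notna(row["patch_id"]) else -1,
                pose_id=int(row["pose_id"]) if "pose_id" in df.columns else int(i),
            )
        )
    return poses


def write_posed_complexes(ref: "ReferenceComplex", poses: list[Pose], path) -> None:
    """Write posed antibody-antigen complexes as a multi-model PDB."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    base = struc.concatenate([ref.ab.atoms, ref.ag.atoms])
    stack = struc.stack([base] * len(poses))
    n_ab = ref.ab.atoms.array_length()
    for m, pose in enumerate(poses):
        stack.coord[m, :n_ab] = pose.apply(ref.ab.coords)
    f = pdbio.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


# --------------------------------------------------------- reference complex
@dataclass
class ReferenceComplex:
    """Model antibody/antigen posed into the native frame; labeling ground truth."""

    ab: Structure
    ag: Structure
    paratope_rmsd: float
    epitope_rmsd: float
    interface_ab: set
    interface_ag: set
    binding_ab: set
    binding_ag: set
    excluded: bool = False
    interface_cutoff: float = 10.0
    binding_cutoff: float = 5.0


def _matched_ca(model: Structure, native: Structure, keys):
    mc, nc = [], []
    for k in sorted(keys):
        try:
            im, iN = model.residue_index(k), native.residue_index(k)
        except KeyError:
            continue
        a, b = model.atom_coord(im, "CA"), native.atom_coord(iN, "CA")
        if a is not None and b is not None:
            mc.append(a)
            nc.append(b)
    return np.asarray(mc), np.asarray(nc)


def build_reference(
    ab_model: Structure,
    ag_model: Structure,
    native_ab: Structure,
    native_ag: Structure,
    paratope_keys,
    epitope_keys,
    max_site_rmsd: float = 6.0,
    interface_cutoff: float = 10.0,
    binding_cutoff: float = 5.0,
) -> ReferenceComplex:
    """Superpose models onto the native via paratope/epitope C-alphas.

    ``paratope_keys``/``epitope_keys`` are the native binding residues (the
    5 A map of the native complex).  The returned reference carries its own
    interface (10 A rule) and binding (5 A) residue sets; ``excluded`` is
    set when either site superposes worse than ``max_site_rmsd``.
    """
    mob_p, tgt_p = _matched_ca(ab_model, native_ab, paratope_keys)
    mob_e, tgt_e = _matched_ca(ag_model, native_ag, epitope_keys)
    if len(mob_p) < 3 or len(mob_e) < 3:
        raise ValueError("need at least 3 mappable paratope and epitope residues")
    Rp, tp, rmsd_p = superpose(mob_p, tgt_p)
    Re, te, rmsd_e = superpose(mob_e, tgt_e)
    ab_posed = ab_model.transformed(Rp, tp)
    ag_posed = ag_model.transformed(Re, te)
    int_ab, int_ag = interface_residues(ab_posed, ag_posed, cutoff=interface_cutoff)
    if not int_ab or not int_ag:
        raise ValueError("reference complex has an empty interface")
    cm = contact_map(ab_posed, ag_posed, cutoff=binding_cutoff)
    excluded = rmsd_p > max_site_rmsd or rmsd_e > max_site_rmsd
    if excluded:
        warnings.warn(
            f"reference excluded: paratope RMSD {rmsd_p:.2f} / epitope RMSD {rmsd_e:.2f} "
            f"exceeds {max_site_rmsd} A"
        )
    return ReferenceComplex(
        ab=ab_posed,
        ag=ag_posed,
        paratope_rmsd=rmsd_p,
        epitope_rmsd=rmsd_e,
        interface_ab=set(int_ab),
        interface_ag=set(int_ag),
        binding_ab=set(cm.ab_residues),
        binding_ag=set(cm.ag_residues),
        excluded=excluded,
        interface_cutoff=interface_cutoff,
        binding_cutoff=binding_cutoff,
    )


# ------------------------------------------------------------------ labeling
@dataclass
class TruePoseCriteria:
    """Thresholds defining a True pose."""

    rmsd_true: float = 15.0
    par_true: float = 0.5
    ep_true: float = 0.5

    def __post_init__(self):
        if self.rmsd_true <= 0 or not (0 <= self.par_true <= 1) or not (0 <= self.ep_true <= 1):
            raise ValueError("invalid True-pose criteria")


def classify_pose_criteria(irmsd_value: float, frac_ab: float, frac_ag: float,
                           crit: TruePoseCriteria) -> bool:
    """Three-way conjunction defining a True pose."""
    return (
        irmsd_value < crit.rmsd_true
        and frac_ab > crit.par_true
        and frac_ag > crit.ep_true
    )


@dataclass
class PoseEvaluation:
    label: bool
    irmsd: float
    frac_true_ab_contacts: float
    frac_true_ag_contacts: float


def label_pose(
    pose: Pose,
    ref: ReferenceComplex,
    crit: TruePoseCriteria | None = None,
    contact_cutoff: float = 5.0,
) -> PoseEvaluation:
    """Label a pose True/False against the reference complex.

    The pose is applied to the reference-posed antibody.  IRMSD is measured
    on the backbone of the reference's antibody interface residues with the
    antigen fixed; the two contact fractions are the precision of the
    pose's own binding sets against the reference binding sets.  A pose
    with no contacts gets fractions 0 and is False.
    """
    crit = crit or TruePoseCriteria()
    posed_ab = ref.ab.transformed(pose.rotation, pose.translation)
    idx = [ref.ab.residue_index(k) for k in sorted(ref.interface_ab)]
    atom_idx = ref.ab.backbone_atom_indices(idx)
    ir = rmsd(posed_ab.coords[atom_idx], ref.ab.coords[atom_idx])
    cm = contact_map(posed_ab, ref.ag, cutoff=contact_cutoff)
    ab_set, ag_set = cm.ab_residues, cm.ag_residues
    frac_ab = len(ab_set & ref.binding_ab) / len(ab_set) if ab_set else 0.0
    frac_ag = len(ag_set & ref.binding_ag) / len(ag_set) if ag_set else 0.0
    return PoseEvaluation(
        label=classify_pose_criteria(ir, frac_ab, frac_ag, crit),
        irmsd=float(ir),
        frac_true_ab_contacts=frac_ab,
        frac_true_ag_contacts=frac_ag,
    )
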