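"""Antibody-specific epitope re-prediction and epitope restraints.

After docking and rescoring, each antigen residue is described by a
docking contact profile: the joint frequency f(i, s) of residue i being in
contact with the antibody in a final cluster representative whose score
falls in bin s (10 equal-width bins over the query's score range,
normalised by the number of representatives).  These 10 columns are
appended to the antigen's conservation / accessibility / surface-shape
blocks and windowed exactly like the initial features; a 7-hidden-layer
network then re-predicts the epitope for this specific antibody.

Restraints act purely at the level of the initial epitope probabilities:
manual per-residue probabilities override the prediction, and an optional
radius zeroes every residue whose C-alpha is farther than that radius from
all manually restrained residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import (
    ConservationProfile,
    ResidueFeatureMatrix,
    build_feature_matrix,
)
from .structure import Structure, contact_map


# ----------------------------------------------------------- contact profile
@dataclass
class DockingContactProfile:
    """Per-residue joint frequency of contact x final-score bin."""

    matrix: np.ndarray  # (n_residues, n_bins)
    bin_edges: np.ndarray  # (n_bins + 1,)
    residue_keys: list

    def __post_init__(self):
        if np.any(self.matrix < 0):
            raise ValueError("profile frequencies must be non-negative")


def docking_profile(
    rep_scores,
    rep_contact_sets,
    ag: Structure,
    n_bins: int = 10,
) -> DockingContactProfile:
    """Build f(i, s) from scored cluster representatives.

    Parameters
    ----------
    rep_scores:
        Final score of each cluster representative.
    rep_contact_sets:
        For each representative, the set of antigen residue keys in contact
        with the antibody in that pose (5 A heavy-atom rule on the posed
        structures).
    """
    scores = np.asarray(rep_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scored representatives")
    lo, hi = float(scores.min()), float(scores.max())
    if hi <= lo:
        warnings.warn("all representative scores identical; degenerate single bin")
        edges = np.linspace(lo - 1.0, lo, n_bins + 1)
        bins = np.full(scores.shape, n_bins - 1, dtype=int)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        bins = np.minimum(np.digitize(scores, edges[1:-1]), n_bins - 1)
    f = np.zeros((ag.n_residues, n_bins))
    for s_bin, contacts in zip(bins, rep_contact_sets):
        for k in contacts:
            f[ag.residue_index(k), s_bin] += 1.0
    f /= len(scores)
    return DockingContactProfile(matrix=f, bin_edges=edges, residue_keys=list(ag.residue_keys))


def representative_contacts(
    ref_ab: Structure, ag: Structure, rep_poses, contact_cutoff: float = 5.0
) -> list[set]:
    """Antigen contact sets of a list of poses applied to the antibody."""
    out = []
    for pose in rep_poses:
        posed = ref_ab.transformed(pose.rotation, pose.translation)
        out.append(set(contact_map(posed, ag, cutoff=contact_cutoff).ag_residues))
    return out


# ------------------------------------------------------------ final features
def build_final_epitope_features(
    ag: Structure,
    profile: ConservationProfile,
    docking: DockingContactProfile,
    **kwargs,
) -> ResidueFeatureMatrix:
    """Windowed antigen features with the 10 docking-profile columns appended
    to every window position's block."""
    if docking.matrix.shape[0] != ag.n_residues:
        raise ValueError("docking profile row count mismatch")
    return build_feature_matrix(
        ag,
        profile,
        mode="final_epitope",
        extra_blocks={"docking": docking.matrix},
        **kwargs,
    )


# ---------------------------------------------------------------- restraints
@dataclass
class RestraintSet:
    """Manual epitope probabilities and an optional exclusion radius."""

    manual: dict = field(default_factory=dict)
    rrest: float | None = None

    def __post_init__(self):
        for k, p in self.manual.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"restraint probability out of range for {k}")
        if self.rrest is not None and self.rrest <= 0:
            raise ValueError("rrest must be positive")

    @classmethod
    def from_tsv(cls, path, rrest: float | None = None) -> "RestraintSet":
        df = pd.read_csv(path, sep="\t")
        manual = {
            (str(r["chain"]), int(r["resnum"]), ""): float(r["probability"])
            for _, r in df.iterrows()
        }
        return cls(manual=manual, rrest=rrest)


def apply_restraints(initial_probs: dict, restraints: RestraintSet, ca_coords: dict) -> dict:
    """Apply manual overrides and the distance cut to epitope probabilities.

    Manual residues take their given probability verbatim.  With ``rrest``
    set, any residue whose C-alpha is farther than ``rrest`` from every
    manually restrained residue is zeroed; all other residues keep their
    initial probability.  Idempotent.
    """
    out = dict(initial_probs)
    missing = [k for k in restraints.manual if k not in out]
    if missing:
        raise KeyError(f"restrained residues absent from antigen: {missing[:3]}")
    for k, p in restraints.manual.items():
        out[k] = p
    if restraints.rrest is not None and restraints.manual:
        anchors = np.asarray([ca_coords[k] for k in restraints.manual], dtype=float)
        for k in out:
            if k in restraints.manual:
                continue
            c = np.asarray(ca_coords[k], dtype=float)
            if np.min(np.linalg.norm(anchors - c, axis=1)) > restraints.rrest:
                out[k] = 0.0
    return out
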