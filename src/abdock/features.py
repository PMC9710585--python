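"""Per-residue feature construction for paratope and epitope prediction.

Each residue of interest is described by concatenating named feature blocks
over a sequence window of +/-5 positions (11 positions total):

* one-hot amino-acid identity (20),
* physico-chemical histogram over the position's own +/-5 sequence
  neighbourhood: fractions of nine overlapping classes (tiny, small,
  aliphatic, aromatic, nonpolar, polar, charged, basic, acidic) plus the
  isoelectric point of that window (10),
* conservation profile row (20),
* solvent accessibility (1, relative by default),
* surface-shape Laplacian norm at five neighbourhood radii (5).

Paratope vectors use all five blocks and are restricted to CDR residues plus
two flanking residues on each side; epitope vectors omit the physchem block
and cover every antigen residue.  Window positions that fall outside the
chain are zero-padded so all rows have fixed width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from Bio.Align import substitution_matrices

from .aa import (
    AA_INDEX,
    AA_ORDER,
    PHYSCHEM_CLASSES,
    PHYSCHEM_ORDER,
    PKA_NEGATIVE,
    PKA_POSITIVE,
)
from .structure import Structure, ResidueKey, contact_map

DEFAULT_LN_RADII = (4.0, 6.0, 8.0, 10.0, 12.0)
WINDOW = 5


# ------------------------------------------------------------------ physchem
def net_charge(sequence: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH."""
    pos = [PKA_POSITIVE["nterm"]] + [PKA_POSITIVE[a] for a in sequence if a in PKA_POSITIVE and a != "nterm"]
    neg = [PKA_NEGATIVE["cterm"]] + [PKA_NEGATIVE[a] for a in sequence if a in PKA_NEGATIVE and a != "cterm"]
    q = sum(1.0 / (1.0 + 10 ** (ph - pk)) for pk in pos)
    q -= sum(1.0 / (1.0 + 10 ** (pk - ph)) for pk in neg)
    return q


def isoelectric_point(sequence: str) -> float:
    """pH at which the peptide's net charge is zero (bisection)."""
    return float(brentq(lambda ph: net_charge(sequence, ph), 0.0, 14.0, xtol=1e-4))


def physchem_histogram(window_sequence: str) -> np.ndarray:
    """Nine overlapping class fractions plus the window isoelectric point.

    Raises
    ------
    ValueError
        If the window is empty after removing nonstandard residues.
    """
    seq = [a for a in window_sequence if a in AA_INDEX]
    if not seq:
        raise ValueError("empty sequence window")
    n = len(seq)
    fracs = [sum(a in PHYSCHEM_CLASSES[c] for a in seq) / n for c in PHYSCHEM_ORDER]
    return np.array(fracs + [isoelectric_point("".join(seq))])


# -------------------------------------------------------------- surface shape
def ln_surface_shape(s: Structure, radii=DEFAULT_LN_RADII) -> np.ndarray:
    """Laplacian-norm curvature of the C-alpha surface at several radii.

    For residue i and radius r, the norm of the displacement between CA_i and
    the Gaussian-weighted (bandwidth r) mean of neighbouring CA positions
    within 3r.  Rigid-motion invariant; residues without CA get zeros.
    """
    ca = s.ca_coords()
    n = s.n_residues
    valid = np.isfinite(ca).all(axis=1)
    if valid.sum() < 2:
        warnings.warn("too few C-alpha atoms for surface shape; zeros returned")
        return np.zeros((n, len(radii)))
    out = np.zeros((n, len(radii)))
    d2 = np.full((n, n), np.inf)
    vi = np.nonzero(valid)[0]
    diff = ca[vi][:, None, :] - ca[vi][None, :, :]
    d2v = np.sum(diff**2, axis=-1)
    for a, i in enumerate(vi):
        d2[i, vi] = d2v[a]
    np.fill_diagonal(d2, np.inf)
    for k, r in enumerate(radii):
        w = np.where(d2 <= (3.0 * r) ** 2, np.exp(-d2 / (2.0 * r * r)), 0.0)
        totals = w.sum(axis=1)
        for i in range(n):
            if not valid[i] or totals[i] <= 0:
                continue
            mean = (w[i, valid][:, None] * ca[valid]).sum(axis=0) / totals[i]
            out[i, k] = np.linalg.norm(ca[i] - mean)
    return out


# --------------------------------------------------------------- conservation
@dataclass
class ConservationProfile:
    """Per-residue 20-column conservation scores (PSSM-like)."""

    matrix: np.ndarray  # (n_residues, 20), columns in AA_ORDER
    source: str = "external"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError("conservation profile must be length x 20")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite conservation scores")

    @classmethod
    def from_tsv(cls, path) -> "ConservationProfile":
        df = pd.read_csv(path, sep=r"\s+")
        cols = [c for c in df.columns if c.upper() in AA_ORDER]
        if len(cols) != 20:
            raise ValueError("PSSM table must have 20 amino-acid columns")
        order = sorted(cols, key=lambda c: AA_INDEX[c.upper()])
        return cls(df[order].to_numpy(), source="external")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, columns=list(AA_ORDER)).to_csv(path, sep="\t", index=False)


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def fallback_conservation(sequence: str) -> ConservationProfile:
    """Substitution-matrix stand-in for an alignment-derived profile.

    Each row is the BLOSUM62 column of the residue's own type, standardised
    to zero mean / unit variance per row.  Nonstandard residues get zero
    rows.  Flagged ``source="fallback"`` so callers can tell it apart from a
    supplied PSSM.
    """
    rows = np.zeros((len(sequence), 20))
    for i, a in enumerate(sequence):
        if a not in AA_INDEX:
            continue
        col = np.array([_BLOSUM62[a][b] for b in AA_ORDER], dtype=float)
        sd = col.std()
        rows[i] = (col - col.mean()) / sd if sd > 0 else 0.0
    return ConservationProfile(rows, source="fallback")


# ------------------------------------------------------------- CDR annotation
@dataclass
class CdrAnnotation:
    """CDR residue ranges on the antibody chains.

    ``regions`` holds ``(chain_id, start_resnum, end_resnum)`` triples
    (inclusive author numbering); ``flank`` residues are added on each side
    when selecting paratope rows.
    """

    regions: list = field(default_factory=list)
    flank: int = 2

    def __post_init__(self):
        for chain, start, end in self.regions:
            if start > end:
                raise ValueError(f"CDR range reversed on chain {chain}: {start} > {end}")

    @classmethod
    def from_tsv(cls, path, flank: int = 2) -> "CdrAnnotation":
        df = pd.read_csv(path, sep="\t")
        regions = [(str(r["chain"]), int(r["start"]), int(r["end"])) for _, r in df.iterrows()]
        return cls(regions=regions, flank=flank)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [
                {"chain": c, "cdr_name": f"CDR{i+1}", "start": s, "end": e}
                for i, (c, s, e) in enumerate(self.regions)
            ]
        ).to_csv(path, sep="\t", index=False)

    def residue_indices(self, s: Structure) -> list[int]:
        """Sorted structure residue indices covered by CDR +/- flank."""
        chosen: set[int] = set()
        for chain, start, end in self.regions:
            in_chain = [
                i for i, k in enumerate(s.residue_keys) if k[0] == chain
            ]
            in_range = [i for i in in_chain if start <= s.residue_keys[i][1] <= end]
            if not in_range:
                continue
            lo = max(0, in_chain.index(in_range[0]) - self.flank)
            hi = min(len(in_chain) - 1, in_chain.index(in_range[-1]) + self.flank)
            chosen.update(in_chain[lo : hi + 1])
        return sorted(chosen)


# ------------------------------------------------------------- feature matrix
@dataclass
class ResidueFeatureMatrix:
    """Windowed per-residue feature rows with named columns."""

    values: np.ndarray
    row_keys: list
    column_names: list
    mode: str

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "chain", [k[0] for k in self.row_keys])
        df.insert(1, "resnum", [k[1] for k in self.row_keys])
        df.to_csv(path, sep="\t", index=False)


def _per_residue_blocks(s: Structure, profile: ConservationProfile, asa_mode: str,
                        ln_radii) -> dict[str, np.ndarray]:
    if profile.matrix.shape[0] != s.n_residues:
        raise ValueError(
            f"profile length {profile.matrix.shape[0]} != {s.n_residues} residues"
        )
    if s.asa is None or s.rsa is None:
        raise ValueError("compute_asa must be called before feature construction")
    n = s.n_residues
    onehot = np.zeros((n, 20))
    for i, a in enumerate(s.sequence):
        if a in AA_INDEX:
            onehot[i, AA_INDEX[a]] = 1.0
    physchem = np.zeros((n, 10))
    chains = s.chain_of_residue
    for i in range(n):
        same = np.nonzero(chains == chains[i])[0]
        pos = int(np.nonzero(same == i)[0][0])
        window = same[max(0, pos - WINDOW) : pos + WINDOW + 1]
        seq = "".join(s.sequence[j] for j in window)
        try:
            physchem[i] = physchem_histogram(seq)
        except ValueError:
            pass
    asa = (s.rsa if asa_mode == "rsa" else s.asa).reshape(-1, 1)
    shape = ln_surface_shape(s, ln_radii)
    return {
        "aa": onehot,
        "physchem": physchem,
        "conservation": profile.matrix,
        "asa": asa,
        "shape": shape,
    }


def window_concat(block: np.ndarray, chains: np.ndarray, rows, window: int = WINDOW) -> np.ndarray:
    """Concatenate per-residue feature blocks over a +/-window, zero-padding
    positions that fall outside the residue's chain."""
    n, width = block.shape
    out = np.zeros((len(rows), (2 * window + 1) * width))
    for r, i in enumerate(rows):
        for o, off in enumerate(range(-window, window + 1)):
            j = i + off
            if 0 <= j < n and chains[j] == chains[i]:
                out[r, o * width : (o + 1) * width] = block[j]
    return out


MODE_BLOCKS = {
    "paratope": ["aa", "physchem", "conservation", "asa", "shape"],
    "epitope": ["aa", "conservation", "asa", "shape"],
    "final_epitope": ["conservation", "asa", "shape", "docking"],
}


def build_feature_matrix(
    s: Structure,
    profile: ConservationProfile,
    cdrs: CdrAnnotation | None = None,
    mode: str = "epitope",
    asa_mode: str = "rsa",
    ln_radii=DEFAULT_LN_RADII,
    extra_blocks: dict | None = None,
    window: int = WINDOW,
) -> ResidueFeatureMatrix:
    """Assemble the windowed feature matrix for one molecule.

    ``mode="paratope"`` requires a CDR annotation and restricts rows to CDR
    residues +/- the annotation's flank; ``mode="epitope"`` covers all
    residues and omits the physchem block.  ``extra_blocks`` lets callers
    append additional per-residue blocks (used by the docking-informed
    re-prediction).
    """
    if mode not in MODE_BLOCKS:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "paratope" and cdrs is None:
        raise ValueError("paratope mode requires a CDR annotation")
    blocks = _per_residue_blocks(s, profile, asa_mode, ln_radii)
    if extra_blocks:
        for name, arr in extra_blocks.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape[0] != s.n_residues:
                raise ValueError(f"extra block {name!r} row count mismatch")
            blocks[name] = arr
    names = MODE_BLOCKS[mode]
    stacked = np.concatenate([blocks[b] for b in names], axis=1)
    widths = [blocks[b].shape[1] for b in names]
    rows = cdrs.residue_indices(s) if mode == "paratope" else list(range(s.n_residues))
    values = window_concat(stacked, s.chain_of_residue, rows, window=window)
    col_names = []
    for off in range(-window, window + 1):
        for b, w in zip(names, widths):
            for j in range(w):
                col_names.append(f"w{off:+d}_{b}{j}")
    return ResidueFeatureMatrix(
        values=values,
        row_keys=[s.residue_keys[i] for i in rows],
        column_names=col_names,
        mode=mode,
    )


# -------------------------------------------------------------------- labels
@dataclass
class BindingLabels:
    """0/1 binding labels per residue at a distance cutoff."""

    labels: dict
    cutoff: float = 5.0

    def positive_keys(self) -> set:
        return {k for k, v in self.labels.items() if v}

    def vector(self, keys) -> np.ndarray:
        return np.array([self.labels.get(k, 0) for k in keys], dtype=int)


def label_binding(ab: Structure, ag: Structure, cutoff: float = 5.0):
    """Binding labels for both molecules from the heavy-atom contact map."""
    cm = contact_map(ab, ag, cutoff=cutoff)
    ab_pos, ag_pos = cm.ab_residues, cm.ag_residues
    ab_labels = {k: int(k in ab_pos) for k in ab.residue_keys}
    ag_labels = {k: int(k in ag_pos) for k in ag.residue_keys}
    return BindingLabels(ab_labels, cutoff), BindingLabels(ag_labels, cutoff)
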