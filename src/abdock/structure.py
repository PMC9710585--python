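"""Structure I/O and geometry primitives.

A :class:`Structure` is a light residue-oriented wrapper around a biotite
``AtomArray`` restricted to heavy atoms of standard amino acids.  All
geometry used downstream — solvent accessibility, least-squares rigid
superposition, contact maps at a distance cutoff, interface residue
selection and interface backbone RMSD (IRMSD) — lives here.

Distances are in Angstrom throughout.  Residues are addressed by the key
``(chain_id, residue_number, insertion_code)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from scipy.spatial import cKDTree

from .aa import BACKBONE_ATOMS, MAX_ASA, NONSTANDARD_PARENT, THREE_TO_ONE

ResidueKey = tuple[str, int, str]


class StructureError(ValueError):
    """Raised for unreadable or inconsistent structural input."""


class Structure:
    """Heavy-atom protein structure organised by residue.

    Parameters
    ----------
    atoms:
        biotite ``AtomArray`` containing only heavy atoms of (mapped)
        standard amino-acid residues.
    id:
        Free-text label, e.g. the source file stem.
    """

    def __init__(self, atoms: struc.AtomArray, id: str = ""):
        if atoms.array_length() == 0:
            raise StructureError("structure contains no atoms")
        self.atoms = atoms
        self.id = id
        starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
        self._starts = starts[:-1]
        self._stops = starts[1:]
        ins = atoms.ins_code if "ins_code" in atoms.get_annotation_categories() else [""] * len(atoms)
        self.residue_keys: list[ResidueKey] = [
            (str(atoms.chain_id[s]), int(atoms.res_id[s]), str(ins[s]))
            for s in self._starts
        ]
        self._key_index = {k: i for i, k in enumerate(self.residue_keys)}
        if len(self._key_index) != len(self.residue_keys):
            raise StructureError("duplicate residue keys within a chain")
        self.residue_names = [str(atoms.res_name[s]) for s in self._starts]
        self.sequence = "".join(THREE_TO_ONE.get(n, "X") for n in self.residue_names)
        self.chain_of_residue = np.array([k[0] for k in self.residue_keys])
        self.asa: np.ndarray | None = None
        self.rsa: np.ndarray | None = None
        if not np.all(np.isfinite(atoms.coord)):
            raise StructureError("non-finite atom coordinates")

    # ------------------------------------------------------------------ basics
    @property
    def n_residues(self) -> int:
        return len(self.residue_keys)

    @property
    def coords(self) -> np.ndarray:
        return self.atoms.coord

    def residue_index(self, key: ResidueKey) -> int:
        return self._key_index[key]

    def residue_atom_slice(self, i: int) -> slice:
        return slice(self._starts[i], self._stops[i])

    def atom_residue_indices(self) -> np.ndarray:
        """Residue index of every atom."""
        out = np.empty(self.atoms.array_length(), dtype=int)
        for i, (s, e) in enumerate(zip(self._starts, self._stops)):
            out[s:e] = i
        return out

    def atom_coord(self, res_index: int, atom_name: str) -> np.ndarray | None:
        sl = self.residue_atom_slice(res_index)
        names = self.atoms.atom_name[sl]
        hit = np.nonzero(names == atom_name)[0]
        if hit.size == 0:
            return None
        return self.atoms.coord[sl][hit[0]]

    def ca_coords(self) -> np.ndarray:
        """(n_residues, 3) C-alpha coordinates, NaN rows where CA is absent."""
        out = np.full((self.n_residues, 3), np.nan)
        for i in range(self.n_residues):
            c = self.atom_coord(i, "CA")
            if c is not None:
                out[i] = c
        return out

    def backbone_coords(self, residue_indices=None, warn_missing: bool = False) -> np.ndarray:
        """Stacked N/CA/C/O coordinates of the selected residues.

        Missing backbone atoms are skipped (optionally with a warning) so the
        result always lines up between structures that share residue content.
        """
        if residue_indices is None:
            residue_indices = range(self.n_residues)
        rows = []
        for i in residue_indices:
            for name in BACKBONE_ATOMS:
                c = self.atom_coord(i, name)
                if c is None:
                    if warn_missing:
                        warnings.warn(
                            f"missing backbone atom {name} in residue {self.residue_keys[i]}"
                        )
                    continue
                rows.append(c)
        return np.asarray(rows).reshape(-1, 3)

    def backbone_atom_indices(self, residue_indices) -> np.ndarray:
        """Global atom indices of N/CA/C/O in the selected residues.

        Useful for fast repeated RMSD evaluation: transform
        ``coords[idx]`` directly instead of rebuilding structures.
        """
        out = []
        for i in residue_indices:
            sl = self.residue_atom_slice(i)
            names = self.atoms.atom_name[sl]
            for name in BACKBONE_ATOMS:
                hit = np.nonzero(names == name)[0]
                if hit.size:
                    out.append(sl.start + int(hit[0]))
        return np.asarray(out, dtype=int)

    # ------------------------------------------------------------- transforms
    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with coordinates ``x @ R.T + t``."""
        atoms = self.atoms.copy()
        atoms.coord = self.atoms.coord @ np.asarray(rotation).T + np.asarray(translation)
        out = Structure(atoms, id=self.id)
        out.asa, out.rsa = self.asa, self.rsa
        return out

    # -------------------------------------------------------------------- I/O
    def to_pdb(self, path: str | Path) -> None:
        f = pdbio.PDBFile()
        f.set_structure(self.atoms)
        f.write(str(path))

    @staticmethod
    def concatenate(*parts: "Structure", id: str = "") -> "Structure":
        arrays = [p.atoms for p in parts]
        return Structure(struc.concatenate(arrays), id=id)


def read_structure(path: str | Path, chain_ids=None, id: str | None = None) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Hetero/solvent records are excluded, hydrogens dropped, alternate
    locations resolved to the highest-occupancy conformer, and common
    nonstandard residues (e.g. MSE) mapped to their standard parent.

    Raises
    ------
    StructureError
        If the file is missing, a requested chain is absent, or no standard
        residues remain.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    pdb_file = pdbio.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1, altloc="occupancy")
    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length():
        atoms = atoms[atoms.element != "H"]
        atoms = atoms[~atoms.hetero | np.isin(atoms.res_name, list(NONSTANDARD_PARENT))]
    # map nonstandard residues to parents, drop unknowns
    names = atoms.res_name.copy() if atoms.array_length() else np.array([])
    keep = np.ones(atoms.array_length(), dtype=bool)
    for i, n in enumerate(names):
        if n in THREE_TO_ONE:
            continue
        if n in NONSTANDARD_PARENT:
            names[i] = NONSTANDARD_PARENT[n]
        else:
            keep[i] = False
    if atoms.array_length():
        atoms.res_name = names
        if not keep.all():
            warnings.warn("dropping atoms of unmapped nonstandard residues")
            atoms = atoms[keep]
    if chain_ids is not None:
        present = set(atoms.chain_id) if atoms.array_length() else set()
        missing = [c for c in chain_ids if c not in present]
        if missing:
            raise StructureError(f"chain(s) {missing} absent from {path.name}")
        atoms = atoms[np.isin(atoms.chain_id, list(chain_ids))]
    if atoms.array_length() == 0:
        raise StructureError(f"no standard amino-acid residues in {path.name}")
    return Structure(atoms, id=id if id is not None else path.stem)


# ------------------------------------------------------------------------ ASA
def compute_asa(
    s: Structure, probe: float = 1.4, point_number: int = 960
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue solvent-accessible surface area and relative ASA.

    Shrake-Rupley sphere sampling (``point_number`` points, element-based van
    der Waals radii).  RSA is ASA divided by the residue type's theoretical
    maximum and clipped to [0, 1].  Results are cached on the structure.
    """
    atom_asa = struc.sasa(
        s.atoms, probe_radius=probe, point_number=point_number, vdw_radii="Single"
    )
    atom_asa = np.nan_to_num(atom_asa)
    res_idx = s.atom_residue_indices()
    asa = np.zeros(s.n_residues)
    np.add.at(asa, res_idx, atom_asa)
    max_asa = np.array([MAX_ASA.get(a, np.mean(list(MAX_ASA.values()))) for a in s.sequence])
    rsa = np.clip(asa / max_asa, 0.0, 1.0)
    s.asa, s.rsa = asa, rsa
    return asa, rsa


# -------------------------------------------------------------- superposition
def superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition (Kabsch).

    Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` best fits
    ``target`` with a proper rotation (det = +1).

    Raises
    ------
    ValueError
        If fewer than 3 point pairs are given or shapes differ.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate sets must both be N x 3")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 point pairs for superposition")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    P, Q = mobile - mc, target - tc
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-8 * max(S[0], 1e-30):
        warnings.warn("degenerate (collinear) point set in superposition")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    fitted = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - target) ** 2, axis=1))))
    return R, t, rmsd


# ---------------------------------------------------------------- contact map
@dataclass(frozen=True)
class ContactMap:
    """Residue-level contacts between two molecules at a distance cutoff."""

    pairs: frozenset  # of (ab ResidueKey, ag ResidueKey)
    cutoff: float

    @property
    def ab_residues(self) -> set:
        return {a for a, _ in self.pairs}

    @property
    def ag_residues(self) -> set:
        return {b for _, b in self.pairs}


def contact_map(ab: Structure, ag: Structure, cutoff: float = 5.0) -> ContactMap:
    """Residue pairs with any heavy-atom pair within ``cutoff``."""
    tree = cKDTree(ag.coords)
    hits = tree.query_ball_point(ab.coords, r=cutoff)
    ab_res = ab.atom_residue_indices()
    ag_res = ag.atom_residue_indices()
    pairs = set()
    for atom_i, lst in enumerate(hits):
        if not lst:
            continue
        ka = ab.residue_keys[ab_res[atom_i]]
        for atom_j in lst:
            pairs.add((ka, ag.residue_keys[ag_res[atom_j]]))
    return ContactMap(pairs=frozenset(pairs), cutoff=cutoff)


def interface_residues(ab: Structure, ag: Structure, cutoff: float = 10.0):
    """Residues of each molecule with any heavy atom within ``cutoff`` of the partner."""
    cm = contact_map(ab, ag, cutoff=cutoff)
    return cm.ab_residues, cm.ag_residues


def clash_count(ab: Structure, ag: Structure, clash_cutoff: float = 2.5) -> int:
    """Number of inter-molecular heavy-atom pairs closer than ``clash_cutoff``."""
    ta, tg = cKDTree(ab.coords), cKDTree(ag.coords)
    # count_neighbors counts pairs at distance <= r; shave an epsilon so the
    # semantics stay "strictly closer than the cutoff".
    return int(ta.count_neighbors(tg, r=clash_cutoff * (1 - 1e-12)))


# ---------------------------------------------------------------------- IRMSD
def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without re-superposition."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("coordinate sets must be non-empty and congruent")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def irmsd(pose_a: Structure, pose_b: Structure, interface_keys) -> float:
    """Backbone RMSD over interface residues of two antibody poses.

    Both poses must already sit in the same (fixed antigen) frame; no
    re-superposition is performed.  ``interface_keys`` selects the antibody
    interface residues on which the RMSD is measured.
    """
    keys = sorted(interface_keys)
    if not keys:
        raise ValueError("empty interface residue set")
    idx = [pose_a.residue_index(k) for k in keys]
    ca = pose_a.backbone_coords(idx, warn_missing=True)
    cb = pose_b.backbone_coords(idx)
    return rmsd(ca, cb)
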