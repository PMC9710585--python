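"""Synthetic antibody-antigen fixtures with planted interfaces and decoys.

Everything downstream of docking consumes geometry, not energetics, so the
generator builds idealised poly-helix (or random-coil) backbones with
pseudo side-chain centroids, poses a two-chain antibody against a
single-chain antigen so that a controlled number of residues are in
contact, and samples decoy pose sets whose interface RMSD to the reference
lands in prescribed "near" and "far" ranges.  Decoy raw energies are a
noisy monotone function of IRMSD so that raw-energy ranking is weakly
informative, emulating the behaviour of raw docking scores.

All randomness flows from the spec seeds; identical specs reproduce
identical fixtures bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .aa import AA_ORDER, ONE_TO_THREE
from .features import CdrAnnotation, BindingLabels, label_binding
from .poses import Pose, ReferenceComplex, build_reference
from .structure import Structure, clash_count, rmsd

_HELIX_OMEGA = np.deg2rad(100.0)
_HELIX_RISE = 1.5

# (radius, phase offset in deg, z offset) of each backbone atom relative to
# the CA helix; idealised, not physical
_ATOM_HELIX = {
    "N": (1.8, -28.0, -0.9),
    "CA": (2.3, 0.0, 0.0),
    "C": (1.7, 28.0, 1.0),
    "O": (2.0, 32.0, 2.2),
    "CB": (3.4, 6.0, -0.5),
}
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
_ATOM_ORDER = ["N", "CA", "C", "O", "CB"]


def _random_sequence(n: int, rng) -> str:
    return "".join(rng.choice(list(AA_ORDER), size=n))


def _chain_atoms(chain_id: str, sequence: str, coords_by_atom: dict) -> struc.AtomArray:
    n = len(sequence)
    per = len(_ATOM_ORDER)
    atoms = struc.AtomArray(n * per)
    atoms.coord = np.zeros((n * per, 3))
    for i in range(n):
        for j, name in enumerate(_ATOM_ORDER):
            a = i * per + j
            atoms.chain_id[a] = chain_id
            atoms.res_id[a] = i + 1
            atoms.res_name[a] = ONE_TO_THREE[sequence[i]]
            atoms.atom_name[a] = name
            atoms.element[a] = _ELEMENTS[name]
            atoms.coord[a] = coords_by_atom[name][i]
    atoms.hetero[:] = False
    return atoms


def _helix_coords(n: int, phase: float, rng, jitter: float = 0.05) -> dict:
    coords = {}
    idx = np.arange(n)
    for name, (radius, dphase, dz) in _ATOM_HELIX.items():
        ang = phase + idx * _HELIX_OMEGA + np.deg2rad(dphase)
        xyz = np.column_stack(
            [radius * np.cos(ang), radius * np.sin(ang), idx * _HELIX_RISE + dz]
        )
        coords[name] = xyz + rng.normal(0.0, jitter, size=xyz.shape)
    return coords


def _coil_coords(n: int, rng, jitter: float = 0.05) -> dict:
    """Persistent random-walk CA trace with interpolated backbone atoms."""
    ca = np.zeros((n, 3))
    d = np.array([1.0, 0.0, 0.0])
    for i in range(1, n):
        d = d + rng.normal(0.0, 0.45, size=3)
        d /= np.linalg.norm(d)
        ca[i] = ca[i - 1] + 3.8 * d
    def unit(v):
        nv = np.linalg.norm(v)
        return v / nv if nv > 0 else np.array([1.0, 0, 0])
    coords = {name: np.zeros((n, 3)) for name in _ATOM_ORDER}
    for i in range(n):
        fwd = unit(ca[min(i + 1, n - 1)] - ca[max(i - 1, 0)])
        side = unit(np.cross(fwd, [0.0, 0.0, 1.0]))
        coords["CA"][i] = ca[i]
        coords["N"][i] = ca[i] - 1.2 * fwd + 0.5 * side
        coords["C"][i] = ca[i] + 1.2 * fwd + 0.4 * side
        coords["O"][i] = ca[i] + 1.4 * fwd + 1.2 * side
        coords["CB"][i] = ca[i] + 1.5 * side - 0.6 * fwd
    for name in coords:
        coords[name] = coords[name] + rng.normal(0.0, jitter, size=(n, 3))
    return coords


def _build_chain(chain_id: str, n: int, geometry: str, rng, phase: float = 0.0) -> Structure:
    seq = _random_sequence(n, rng)
    if geometry == "helix":
        coords = _helix_coords(n, phase, rng)
    elif geometry == "coil":
        coords = _coil_coords(n, rng)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return Structure(_chain_atoms(chain_id, seq, coords), id=chain_id)


def _rigid(structure: Structure, R: np.ndarray, t: np.ndarray) -> Structure:
    return structure.transformed(R, t)


def _random_rotation(rng) -> np.ndarray:
    return Rotation.random(rng=rng).as_matrix()


# ----------------------------------------------------------------- complexes
@dataclass
class ToyComplexSpec:
    """Conditions for one synthetic antibody-antigen complex."""

    ab_lengths: tuple = (50, 45)
    ag_length: int = 60
    interface_size: int = 10
    geometry: str = "helix"
    model_noise: float = 0.2  # A, per-atom jitter of the "homology models"
    seed: int = 0

    def __post_init__(self):
        if self.interface_size > min(min(self.ab_lengths), self.ag_length):
            raise ValueError("interface_size exceeds chain length")


@dataclass
class ToyComplex:
    """A planted-interface complex plus its imperfect models."""

    ab: Structure          # native-frame antibody (chains H, L)
    ag: Structure          # native-frame antigen (chain A)
    ab_model: Structure    # jittered model in its own frame
    ag_model: Structure
    cdrs: CdrAnnotation
    ab_labels: BindingLabels
    ag_labels: BindingLabels
    spec: ToyComplexSpec

    def reference(self, **kwargs) -> ReferenceComplex:
        return build_reference(
            self.ab_model,
            self.ag_model,
            self.ab,
            self.ag,
            paratope_keys=self.ab_labels.positive_keys(),
            epitope_keys=self.ag_labels.positive_keys(),
            **kwargs,
        )

    def write_dir(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.ab.to_pdb(out / "native_ab.pdb")
        self.ag.to_pdb(out / "native_ag.pdb")
        Structure.concatenate(self.ab, self.ag, id="native").to_pdb(out / "native_complex.pdb")
        self.ab_model.to_pdb(out / "ab_model.pdb")
        self.ag_model.to_pdb(out / "ag_model.pdb")
        self.cdrs.to_tsv(out / "cdrs.tsv")


def _contact_ranges(keys, chain: str, gap: int = 4) -> list:
    nums = sorted(k[1] for k in keys if k[0] == chain)
    ranges = []
    for n in nums:
        if ranges and n - ranges[-1][1] <= gap:
            ranges[-1][1] = n
        else:
            ranges.append([n, n])
    return [(chain, a, b) for a, b in ranges]


def make_toy_complex(spec: ToyComplexSpec) -> ToyComplex:
    """Generate a toy complex with ~``interface_size`` contacting antigen residues.

    The antibody heavy chain is slid toward the antigen helix until the
    planted interface reaches the requested size without steric clashes;
    the light chain packs alongside without touching the antigen.  CDR
    ranges are derived from the contacting antibody residues.  The
    homology-model stand-ins are jittered, rigidly displaced copies.
    """
    rng = np.random.default_rng(spec.seed)
    ag = _build_chain("A", spec.ag_length, spec.geometry, rng, phase=rng.uniform(0, 2 * np.pi))
    h = _build_chain("H", spec.ab_lengths[0], "helix", rng, phase=rng.uniform(0, 2 * np.pi))
    light = _build_chain("L", spec.ab_lengths[1], "helix", rng, phase=rng.uniform(0, 2 * np.pi))

    # plant the interface at a random offset along the antigen so that no
    # position on the antigen is a-priori more epitope-like than another
    z_shift = (
        (spec.ag_length - spec.ab_lengths[0]) * _HELIX_RISE / 2.0
        + rng.uniform(-8.0, 8.0)
    )
    ag_tree = cKDTree(ag.coords)
    ag_res_of_atom = ag.atom_residue_indices()
    chosen = None
    for d in np.arange(16.0, 6.0, -0.2):
        moved = h.transformed(np.eye(3), np.array([d, 0.0, z_shift]))
        dist, _ = ag_tree.query(moved.coords)
        if dist.min() < 2.7:  # steric clash; keep the previous placement
            break
        hits = ag_tree.query_ball_point(moved.coords, 5.0)
        n_contact_ag = len({ag_res_of_atom[j] for lst in hits for j in lst})
        chosen = (d, moved, n_contact_ag)
        if n_contact_ag >= spec.interface_size:
            break
    if chosen is None:
        raise ValueError("geometrically infeasible complex spec")
    d, h_posed, _ = chosen
    l_posed = light.transformed(
        np.eye(3), np.array([d + 7.0, 11.0, z_shift + rng.uniform(-3.0, 3.0)])
    )
    ab = Structure.concatenate(h_posed, l_posed, id="ab")

    # random global frame for the whole native complex
    Rg, tg = _random_rotation(rng), rng.uniform(-20, 20, size=3)
    ab = _rigid(ab, Rg, tg)
    ag = _rigid(ag, Rg, tg)

    ab_labels, ag_labels = label_binding(ab, ag, cutoff=5.0)
    regions = _contact_ranges(ab_labels.positive_keys(), "H")
    regions += _contact_ranges(ab_labels.positive_keys(), "L")
    if not any(c == "L" for c, _, _ in regions):
        mid = spec.ab_lengths[1] // 2
        regions.append(("L", mid - 2, mid + 2))
    if not regions:
        raise ValueError("planted interface produced no antibody contacts")
    cdrs = CdrAnnotation(regions=regions, flank=2)

    def model_of(s: Structure) -> Structure:
        atoms = s.atoms.copy()
        atoms.coord = atoms.coord + rng.normal(0.0, spec.model_noise, size=atoms.coord.shape)
        out = Structure(atoms, id=s.id + "_model")
        return _rigid(out, _random_rotation(rng), rng.uniform(-30, 30, size=3))

    return ToyComplex(
        ab=ab, ag=ag,
        ab_model=model_of(ab), ag_model=model_of(ag),
        cdrs=cdrs, ab_labels=ab_labels, ag_labels=ag_labels,
        spec=spec,
    )


# -------------------------------------------------------------------- decoys
@dataclass
class DecoySpec:
    """Conditions for a synthetic decoy pose set."""

    n_poses: int = 1000
    true_fraction: float = 0.05
    irmsd_range_true: tuple = (1.0, 12.0)
    irmsd_range_false: tuple = (15.0, 80.0)
    engine_mix: float = 0.9  # fraction of poses tagged with the global engine
    energy_noise_sd: float = 75.0
    contact_gap: tuple = (3.5, 4.3)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.true_fraction <= 1.0 and 0.0 <= self.engine_mix <= 1.0):
            raise ValueError("fractions must be in [0, 1]")
        for lo, hi in (self.irmsd_range_true, self.irmsd_range_false):
            if not (0 < lo < hi):
                raise ValueError("IRMSD ranges must be positive and ordered")


# Near poses must be native-like in the liberal sense used for labeling:
# besides the IRMSD window, the pose's contacts must still mostly overlap the
# reference binding sets.  Precision floor used when planting near poses:
_PLANT_PRECISION = 0.5


def _near_pose(rng, B, centroid, target, lo, hi, fracs):
    """Perturbation about the interface centroid, rejection-sampled so the
    IRMSD lands in [lo, hi] while the pose keeps majority-true contacts.

    If a target IRMSD proves incompatible with the contact-precision floor
    the target is progressively resampled toward the low end of the range.
    """
    lever = np.sqrt(np.mean(np.sum((B - centroid) ** 2, axis=1)))
    for _round in range(8):
        for _ in range(40):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            theta = min(target / max(lever, 1e-6) * rng.uniform(0.5, 1.0), 1.0)
            R = Rotation.from_rotvec(axis * theta).as_matrix()
            rot_irmsd = rmsd((B - centroid) @ R.T + centroid, B)
            if rot_irmsd > target:
                theta *= 0.8 * target / rot_irmsd
                R = Rotation.from_rotvec(axis * theta).as_matrix()
                rot_irmsd = rmsd((B - centroid) @ R.T + centroid, B)
            remaining = np.sqrt(max(target**2 - rot_irmsd**2, 0.0))
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            t = centroid - R @ centroid + remaining * u
            measured = rmsd(B @ R.T + t, B)
            if not (lo <= measured <= hi):
                continue
            frac_ab, frac_ag = fracs(R, t)
            if frac_ab > _PLANT_PRECISION and frac_ag > _PLANT_PRECISION:
                return R, t, measured
        target = rng.uniform(lo, max(lo * 1.01, target * 0.6))
    raise RuntimeError("near-pose sampling failed; interface too small?")


def _far_pose(rng, ab_shell, ab_centroid, ag_coords, ag_centroid, B, gap, lo, hi):
    """Random orientation slid into surface contact from a random direction.

    ``ab_shell`` holds the antibody's outer (convex-hull) atoms, which are
    the ones that can make first contact while sliding.
    """
    for _ in range(120):
        R = Rotation.random(rng=rng).as_matrix()
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        A0 = (ab_shell - ab_centroid) @ R.T + ag_centroid
        b = A0[:, None, :] - ag_coords[None, :, :]
        bu = np.einsum("ijk,k->ij", b, u)
        disc = bu**2 - np.sum(b**2, axis=-1) + gap**2
        real = disc > 0
        if not real.any():
            continue
        t_star = float(np.max(-bu[real] + np.sqrt(disc[real])))
        t = ag_centroid - R @ ab_centroid + t_star * u
        measured = rmsd(B @ R.T + t, B)
        if lo <= measured <= hi:
            return R, t, measured
    raise RuntimeError("far-pose sampling failed; antigen geometry too small?")


def make_decoys(ref: ReferenceComplex, spec: DecoySpec) -> list[Pose]:
    """Sample a decoy pose table around a reference complex.

    ``spec.true_fraction`` of poses are near-reference (IRMSD in
    ``irmsd_range_true``), the rest land elsewhere on the antigen surface
    (IRMSD in ``irmsd_range_false``).  Raw energy is IRMSD plus Gaussian
    noise (lower is better), per-engine tags follow ``engine_mix``, and the
    returned order is shuffled.
    """
    rng = np.random.default_rng(spec.seed)
    idx = [ref.ab.residue_index(k) for k in sorted(ref.interface_ab)]
    atom_idx = ref.ab.backbone_atom_indices(idx)
    B = np.asarray(ref.ab.coords[atom_idx], dtype=float)
    centroid = B.mean(axis=0)
    ab_coords = np.asarray(ref.ab.coords, dtype=float)
    ag_coords = np.asarray(ref.ag.coords, dtype=float)
    ab_centroid = ab_coords.mean(axis=0)
    ag_centroid = ag_coords.mean(axis=0)
    from scipy.spatial import ConvexHull

    ab_shell = ab_coords[ConvexHull(ab_coords).vertices]

    # fast contact-precision evaluation against the reference binding sets
    ag_tree = cKDTree(ag_coords)
    ab_res_of_atom = ref.ab.atom_residue_indices()
    ag_res_of_atom = ref.ag.atom_residue_indices()
    bind_ab_idx = {ref.ab.residue_index(k) for k in ref.binding_ab}
    bind_ag_idx = {ref.ag.residue_index(k) for k in ref.binding_ag}

    def fracs(R, t):
        hits = ag_tree.query_ball_point(ab_coords @ R.T + t, ref.binding_cutoff)
        ab_set, ag_set = set(), set()
        for ai, lst in enumerate(hits):
            if lst:
                ab_set.add(ab_res_of_atom[ai])
                ag_set.update(ag_res_of_atom[j] for j in lst)
        fa = len(ab_set & bind_ab_idx) / len(ab_set) if ab_set else 0.0
        fg = len(ag_set & bind_ag_idx) / len(ag_set) if ag_set else 0.0
        return fa, fg

    n_true = int(round(spec.n_poses * spec.true_fraction))
    poses = []
    for i in range(spec.n_poses):
        if i < n_true:
            target = rng.uniform(*spec.irmsd_range_true)
            R, t, measured = _near_pose(
                rng, B, centroid, target, *spec.irmsd_range_true, fracs=fracs
            )
        else:
            gap = rng.uniform(*spec.contact_gap)
            R, t, measured = _far_pose(
                rng, ab_shell, ab_centroid, ag_coords, ag_centroid, B,
                gap, *spec.irmsd_range_false,
            )
        engine = "piper" if rng.random() < spec.engine_mix else "hex"
        poses.append(
            Pose(
                rotation=R,
                translation=t,
                engine=engine,
                raw_energy=float(measured + rng.normal(0.0, spec.energy_noise_sd)),
                patch_id=int(rng.integers(0, 3)) if engine == "hex" else -1,
                irmsd_to_ref=float(measured),
            )
        )
    order = rng.permutation(spec.n_poses)
    shuffled = [poses[i] for i in order]
    for pid, p in enumerate(shuffled):
        p.pose_id = pid
    return shuffled
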