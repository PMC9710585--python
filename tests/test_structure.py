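"""Geometry primitives: I/O round-trips, ASA, superposition, contacts, IRMSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from abdock.structure import (
    Structure,
    StructureError,
    clash_count,
    compute_asa,
    contact_map,
    interface_residues,
    irmsd,
    read_structure,
    superpose,
)

from conftest import ca_only_chain, chain_structure


# ------------------------------------------------------------------- reading
def _write_toy_pdb(tmp_path, toy_complex):
    path = tmp_path / "toy.pdb"
    toy_complex.ag.to_pdb(path)
    return path


class TestReadStructure:
    def test_round_trip_preserves_residues_and_coords(self, tmp_path, toy_complex):
        path = _write_toy_pdb(tmp_path, toy_complex)
        s = read_structure(path)
        assert s.n_residues == toy_complex.ag.n_residues
        assert np.allclose(s.coords, toy_complex.ag.coords, atol=1e-2)
        s2 = read_structure(path)
        assert np.array_equal(s.coords, s2.coords)  # bitwise determinism

    def test_missing_chain_raises(self, tmp_path, toy_complex):
        path = _write_toy_pdb(tmp_path, toy_complex)
        with pytest.raises(StructureError, match="Z"):
            read_structure(path, chain_ids=["Z"])

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(StructureError, match="no such file"):
            read_structure(tmp_path / "absent.pdb")


# ----------------------------------------------------------------------- ASA
class TestComputeAsa:
    def test_isolated_residue_fully_exposed(self):
        s = chain_structure(
            [{"N": [0.0, 1.4, 0], "CA": [0, 0, 0], "C": [1.5, 0, 0], "O": [2.2, 1.0, 0]}],
            res_names=["GLY"],
        )
        _, rsa = compute_asa(s)
        assert 0.9 <= rsa[0] <= 1.1

    def test_enclosed_residue_has_zero_asa(self):
        # glycine at the origin inside a synthetic shell of carbon atoms
        shell = []
        golden = np.pi * (3 - np.sqrt(5))
        for i in range(200):
            z = 1 - 2 * (i + 0.5) / 200
            r = np.sqrt(1 - z * z)
            phi = golden * i
            shell.append({"CB": 4.0 * np.array([r * np.cos(phi), r * np.sin(phi), z])})
        s = chain_structure([{"CA": [0.0, 0, 0]}] + shell)
        asa, _ = compute_asa(s)
        assert asa[0] == 0.0

    def test_matches_sphere_sampling_oracle(self, toy_complex):
        """Independent Shrake-Rupley re-implementation agrees within 5%."""
        s = toy_complex.ag
        asa, _ = compute_asa(s)
        oracle = _asa_oracle(s, n_points=960)
        total, total_o = asa.sum(), oracle.sum()
        assert abs(total - total_o) / total_o < 0.05
        big = oracle > 20  # avoid ratio blow-ups on tiny areas
        assert np.allclose(asa[big], oracle[big], rtol=0.10)

    def test_total_asa_invariant_under_rigid_motion(self, toy_complex):
        # invariance holds to the resolution of the fixed 960-point sphere
        # grid; rotating the molecule re-discretises the surface slightly
        s = toy_complex.ag
        asa, _ = compute_asa(s)
        R = Rotation.from_euler("zyx", [11, 23, -7], degrees=True).as_matrix()
        asa2, _ = compute_asa(s.transformed(R, np.array([5.0, -3.0, 2.0])))
        assert np.isclose(asa.sum(), asa2.sum(), rtol=5e-3)


def _asa_oracle(s, n_points=960, probe=1.4):
    """Brute-force sphere-point ASA, independent of the library routine."""
    radii = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
    coords = np.asarray(s.coords, dtype=float)
    elements = s.atoms.element
    r = np.array([radii.get(e, 1.7) for e in elements]) + probe
    i = np.arange(n_points)
    golden = np.pi * (3 - np.sqrt(5))
    z = 1 - 2 * (i + 0.5) / n_points
    rho = np.sqrt(1 - z**2)
    sphere = np.column_stack([rho * np.cos(golden * i), rho * np.sin(golden * i), z])
    per_atom = np.zeros(len(coords))
    for a in range(len(coords)):
        pts = coords[a] + r[a] * sphere
        d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=-1)
        d[:, a] = np.inf
        exposed = np.all(d >= r[None, :], axis=1)
        per_atom[a] = exposed.mean() * 4 * np.pi * r[a] ** 2
    res_idx = s.atom_residue_indices()
    out = np.zeros(s.n_residues)
    np.add.at(out, res_idx, per_atom)
    return out


# -------------------------------------------------------------- superposition
class TestSuperpose:
    def test_identity_on_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        R, t, r = superpose(pts, pts)
        assert r < 1e-9
        assert np.allclose(R, np.eye(3), atol=1e-9)

    def test_recovers_planted_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3)) * 5
        R0 = Rotation.from_euler("xyz", [30, 0, 0], degrees=True).as_matrix()
        t0 = np.array([1.0, -2.0, 3.0])
        R, t, r = superpose(pts, pts @ R0.T + t0)
        assert r < 1e-6
        assert np.allclose(R, R0, atol=1e-6)
        assert np.allclose(t, t0, atol=1e-6)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        _, _, r = superpose(a, b)
        rot, oracle_rssd = Rotation.align_vectors(
            b - b.mean(axis=0), a - a.mean(axis=0)
        )
        assert np.isclose(r, oracle_rssd / np.sqrt(10), atol=1e-8)

    def test_requires_three_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_warn(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.warns(UserWarning, match="degenerate"):
            superpose(line, line + 1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(9, 3)), rng.normal(size=(9, 3))
        R, t, _ = superpose(a, b)
        fitted = a @ R.T + t
        _, _, r2 = superpose(fitted, b)
        R2, t2, _ = superpose(fitted, fitted)
        assert np.allclose(R2, np.eye(3), atol=1e-9) and np.allclose(t2, 0, atol=1e-9)


# ----------------------------------------------------------- contacts / IRMSD
class TestContacts:
    @pytest.mark.parametrize("gap,expected", [(4.9, True), (5.1, False)])
    def test_cutoff_semantics(self, gap, expected):
        a = chain_structure([{"CA": [0.0, 0, 0]}])
        b = chain_structure([{"CA": [gap, 0, 0]}], chain="B")
        cm = contact_map(a, b, cutoff=5.0)
        assert bool(cm.pairs) is expected

    def test_separated_structures_empty(self):
        a = ca_only_chain([[0, 0, 0], [3.8, 0, 0]])
        b = ca_only_chain([[100.0, 0, 0], [103.8, 0, 0]], chain="B")
        assert not contact_map(a, b).pairs
        ia, ig = interface_residues(a, b)
        assert not ia and not ig

    def test_matches_brute_force_scan(self, toy_complex):
        ab, ag = toy_complex.ab, toy_complex.ag
        cm = contact_map(ab, ag, cutoff=5.0)
        assert cm.pairs == _brute_force_pairs(ab, ag, 5.0)

    def test_projections_are_consistent(self, toy_complex):
        cm = contact_map(toy_complex.ab, toy_complex.ag)
        for a in cm.ab_residues:
            assert any(p[0] == a for p in cm.pairs)
        for g in cm.ag_residues:
            assert any(p[1] == g for p in cm.pairs)

    def test_planted_interface_recovered(self, toy_complex):
        _, ig = interface_residues(toy_complex.ab, toy_complex.ag, cutoff=5.0)
        assert set(ig) == toy_complex.ag_labels.positive_keys()
        assert len(ig) >= toy_complex.spec.interface_size

    def test_clash_count_matches_brute_force(self, toy_complex):
        rng = np.random.default_rng(5)
        for _ in range(3):
            shift = rng.normal(scale=3.0, size=3)
            moved = toy_complex.ab.transformed(np.eye(3), shift)
            expected = _brute_force_clashes(moved, toy_complex.ag, 2.5)
            assert clash_count(moved, toy_complex.ag, 2.5) == expected


def _brute_force_pairs(ab, ag, cutoff):
    ares, gres = ab.atom_residue_indices(), ag.atom_residue_indices()
    d = np.linalg.norm(ab.coords[:, None, :] - ag.coords[None, :, :], axis=-1)
    pairs = set()
    for i, j in zip(*np.nonzero(d <= cutoff)):
        pairs.add((ab.residue_keys[ares[i]], ag.residue_keys[gres[j]]))
    return pairs


def _brute_force_clashes(ab, ag, cutoff):
    d = np.linalg.norm(
        np.asarray(ab.coords, float)[:, None, :] - np.asarray(ag.coords, float)[None, :, :],
        axis=-1,
    )
    return int((d < cutoff).sum())


class TestIrmsd:
    def test_zero_on_identity(self, toy_complex):
        s = toy_complex.ab
        assert irmsd(s, s, s.residue_keys[:10]) == 0.0

    def test_pure_translation_is_exact(self, toy_complex):
        s = toy_complex.ab
        moved = s.transformed(np.eye(3), np.array([3.0, 0.0, 0.0]))
        assert np.isclose(irmsd(s, moved, s.residue_keys), 3.0, atol=1e-5)

    def test_matches_direct_formula(self, toy_complex):
        s = toy_complex.ab
        rng = np.random.default_rng(8)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(size=3)
        moved = s.transformed(R, t)
        keys = s.residue_keys[:12]
        idx = [s.residue_index(k) for k in keys]
        a = s.backbone_coords(idx)
        b = moved.backbone_coords(idx)
        expected = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        assert np.isclose(irmsd(s, moved, keys), expected, rtol=1e-6)

    def test_pseudo_metric_properties(self, toy_complex):
        s = toy_complex.ab
        rng = np.random.default_rng(9)
        keys = s.residue_keys[:15]
        poses = [
            s.transformed(Rotation.random(rng=rng).as_matrix(), rng.normal(size=3) * 4)
            for _ in range(4)
        ]
        for i in range(4):
            for j in range(4):
                dij = irmsd(poses[i], poses[j], keys)
                assert np.isclose(dij, irmsd(poses[j], poses[i], keys), rtol=1e-9)
                for k in range(4):
                    assert dij <= irmsd(poses[i], poses[k], keys) + irmsd(
                        poses[k], poses[j], keys
                    ) + 1e-9

    def test_empty_interface_raises(self, toy_complex):
        with pytest.raises(ValueError, match="empty interface"):
            irmsd(toy_complex.ab, toy_complex.ab, [])
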