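"""Binding-site extraction, Kabsch superposition and site RMSD matrices."""

import itertools

import numpy as np
import pytest

from conftest import atom, random_rotation, structure
from kinsel.structures import (
    DegenerateSuperpositionError,
    DistanceMatrix,
    NoReferenceLigandError,
    StructureRecord,
    consensus_site,
    extract_binding_site,
    kabsch,
    match_site_atoms,
    pairwise_rmsd_matrix,
    read_structures,
    superpose,
    superpose_ensemble,
    write_structure,
)


class TestExtractBindingSite:
    def test_residue_inside_cutoff_included(self):
        s = structure(
            "s1",
            {1: [("CA", (4.9, 0, 0))], 2: [("CA", (5.1, 0, 0))]},
            [("C1", "C", (0, 0, 0))],
        )
        site = extract_binding_site(s, cutoff=5.0)
        assert ("A", 1, "") in site.member_residue_ids
        assert ("A", 2, "") not in site.member_residue_ids

    def test_hydrogens_do_not_define_the_site(self):
        # residue whose only atom within the cutoff is a hydrogen
        s = structure("s1", {1: [("CA", (8.0, 0, 0))]}, [("C1", "C", (0, 0, 0))])
        s.protein_atoms.append(atom("H", "H", ("A", 1, ""), (3.0, 0, 0)))
        site = extract_binding_site(s, cutoff=5.0)
        assert site.member_residue_ids == set()

    def test_no_ligand_raises(self):
        s = structure("s1", {1: [("CA", (0, 0, 0))]})
        with pytest.raises(NoReferenceLigandError):
            extract_binding_site(s)

    def test_matches_brute_force_distance_scan(self, rng):
        """Exact member set versus an all-pairs distance scan oracle."""
        for _ in range(25):
            n_res = int(rng.integers(3, 10))
            prot = {
                r + 1: [
                    (f"C{a}", rng.uniform(-8, 8, 3))
                    for a in range(int(rng.integers(1, 5)))
                ]
                for r in range(n_res)
            }
            lig = [(f"L{i}", "C", rng.uniform(-3, 3, 3)) for i in range(3)]
            s = structure("s", prot, lig)
            site = extract_binding_site(s, cutoff=5.0)
            expected = set()
            for num, atoms in prot.items():
                for _, pxyz in atoms:
                    for _, _, lxyz in lig:
                        if np.linalg.norm(np.array(pxyz) - np.array(lxyz)) <= 5.0:
                            expected.add(("A", num, ""))
            assert site.member_residue_ids == expected

    def test_monotone_in_cutoff(self, rng):
        prot = {r + 1: [("CA", rng.uniform(-10, 10, 3))] for r in range(20)}
        s = structure("s", prot, [("C1", "C", (0, 0, 0))])
        small = extract_binding_site(s, cutoff=4.0).member_residue_ids
        large = extract_binding_site(s, cutoff=5.0).member_residue_ids
        assert small <= large


def _grid_search_rmsd(ref, mob, levels=5, steps=11):
    """Independent oracle: nested grid search over Euler rotations.

    Both point sets are centered (the optimal translation for any fixed
    rotation matches centroids), then z-y-x Euler angles are refined over
    shrinking windows.
    """
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)

    def rot(a, b, c):
        ca, sa, cb, sb, cc, sc = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(c), np.sin(c)
        Rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        Rx = np.array([[1, 0, 0], [0, cc, -sc], [0, sc, cc]])
        return Rz @ Ry @ Rx

    def rmsd(angles):
        R = rot(*angles)
        return np.sqrt(np.mean(np.sum(((R @ mob_c.T).T - ref_c) ** 2, axis=1)))

    centre = np.zeros(3)
    width = np.pi
    best = rmsd(centre)
    for _ in range(levels):
        grid = [np.linspace(c - width, c + width, steps) for c in centre]
        for angles in itertools.product(*grid):
            r = rmsd(angles)
            if r < best:
                best, centre = r, np.array(angles)
        width /= steps / 2.5
    return best


class TestSuperpose:
    def _toy(self):
        return np.array(
            [[0, 0, 0], [2, 0, 0], [0, 2, 0], [0.3, 0.4, 1.7]], dtype=float
        )

    def test_translated_copy_fits_exactly(self):
        ref = self._toy()
        _, _, rmsd = kabsch(ref, ref + np.array([5.0, 0, 0]))
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rotated_copy_fits_exactly(self):
        ref = self._toy()
        Rz = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        _, _, rmsd = kabsch(ref, (Rz @ ref.T).T)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rotation_is_proper(self, rng):
        ref = rng.normal(size=(6, 3))
        mob = rng.normal(size=(6, 3))
        R, _, _ = kabsch(ref, mob)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)

    def test_displaced_atom_matches_grid_search_oracle(self):
        ref = self._toy()
        mob = ref.copy()
        mob[3] += np.array([0.8, -0.5, 0.3])
        _, _, rmsd = kabsch(ref, mob)
        oracle = _grid_search_rmsd(ref, mob)
        assert rmsd == pytest.approx(oracle, abs=1e-3)
        assert rmsd <= oracle + 1e-9  # least-squares minimum

    def test_invariant_under_rigid_pretransform(self, rng):
        ref = rng.normal(size=(8, 3))
        mob = ref + rng.normal(0, 0.4, size=(8, 3))
        _, _, r0 = kabsch(ref, mob)
        for _ in range(5):
            Q = random_rotation(rng)
            t = rng.uniform(-20, 20, 3)
            _, _, r1 = kabsch(ref, (Q @ mob.T).T + t)
            assert r1 == pytest.approx(r0, abs=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DegenerateSuperpositionError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_pairs_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(DegenerateSuperpositionError):
            kabsch(line, line)

    def test_superpose_structures(self):
        ref = structure(
            "ref", {1: [("CA", (0, 0, 0))], 2: [("CA", (2, 0, 0))], 3: [("CA", (0, 2, 0))]}
        )
        mob = structure(
            "mob", {1: [("CA", (1, 1, 0))], 2: [("CA", (3, 1, 0))], 3: [("CA", (1, 3, 0))]}
        )
        pairs = list(zip(ref.protein_atoms, mob.protein_atoms))
        fitted, rmsd = superpose(ref, mob, pairs)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(fitted.protein_atoms[0].coords, (0, 0, 0), atol=1e-10)


def _shifted(sid, base, shift):
    return structure(
        sid, {num: [(n, np.asarray(x) + shift) for n, x in atoms] for num, atoms in base.items()}
    )


class TestPairwiseRmsdMatrix:
    BASE = {
        1: [("CA", (0.0, 0, 0)), ("CB", (1.0, 0, 0))],
        2: [("CA", (0.0, 3, 0))],
    }
    SITE = {("A", 1, ""), ("A", 2, "")}

    def test_duplicate_structure_distance_zero(self):
        a = _shifted("a", self.BASE, (0, 0, 0))
        b = _shifted("b", self.BASE, (0, 0, 0))
        D = pairwise_rmsd_matrix([a, b], self.SITE)
        assert D.values[0, 1] == pytest.approx(0.0)

    def test_uniform_shift_gives_shift_magnitude(self):
        a = _shifted("a", self.BASE, (0, 0, 0))
        b = _shifted("b", self.BASE, (1, 0, 0))
        D = pairwise_rmsd_matrix([a, b], self.SITE)
        assert D.values[0, 1] == pytest.approx(1.0)

    def test_matches_per_atom_hand_summation(self, rng):
        """Three structures against a direct sqrt(mean squared d) oracle."""
        structs = []
        coords = {}
        for sid in ("a", "b", "c"):
            base = {
                num: [(n, np.asarray(x) + rng.normal(0, 1, 3)) for n, x in atoms]
                for num, atoms in self.BASE.items()
            }
            structs.append(structure(sid, base))
            coords[sid] = base
        D = pairwise_rmsd_matrix(structs, self.SITE)
        for i, si in enumerate("abc"):
            for j, sj in enumerate("abc"):
                if i >= j:
                    continue
                sq = [
                    np.sum((np.asarray(xi) - np.asarray(xj)) ** 2)
                    for num in self.BASE
                    for (ni, xi), (nj, xj) in zip(coords[si][num], coords[sj][num])
                ]
                assert D.values[i, j] == pytest.approx(np.sqrt(np.mean(sq)))

    def test_permutation_equivariant(self, rng):
        structs = [
            _shifted(sid, self.BASE, rng.normal(0, 1, 3)) for sid in ("a", "b", "c")
        ]
        D1 = pairwise_rmsd_matrix(structs, self.SITE)
        D2 = pairwise_rmsd_matrix(structs[::-1], self.SITE)
        assert D2.labels == D1.labels[::-1]
        assert np.allclose(D2.values, D1.values[::-1, ::-1])

    def test_disjoint_site_atoms_error_names_pair(self):
        a = structure("a", {1: [("CA", (0, 0, 0)), ("CB", (1, 1, 1))]})
        b = structure("b", {2: [("CA", (0, 0, 0))]})
        with pytest.raises(ValueError, match="a and b"):
            pairwise_rmsd_matrix([a, b], {("A", 1, ""), ("A", 2, "")})


class TestDistanceMatrixIO:
    def test_tsv_round_trip(self, tmp_path, rng):
        pts = rng.normal(size=(4, 2))
        from scipy.spatial.distance import squareform, pdist

        values = squareform(pdist(pts))
        D = DistanceMatrix(["w", "x", "y", "z"], values)
        D.to_tsv(tmp_path / "d.tsv")
        back = DistanceMatrix.from_tsv(tmp_path / "d.tsv")
        assert back.labels == D.labels
        assert np.allclose(back.values, D.values, atol=1e-6)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


PDB_FIXTURE = """\
ATOM      1  N   ALA A   1      11.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1      12.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA BALA A   1      12.500   0.000   0.000  0.60  0.00           C
ATOM      4  CA  GLY A   2       2.000   1.000   0.000  1.00  0.00           C
HETATM    5  C1  XYZ A 101       0.000   0.000   0.000  1.00  0.00           C
HETATM    6  C2  XYZ A 101       1.400   0.000   0.000  1.00  0.00           C
HETATM    7  O   HOH A 201       3.000   3.000   3.000  1.00  0.00           O
HETATM    8  S   SO4 A 202       4.000   4.000   4.000  1.00  0.00           S
END
"""


class TestPdbInput:
    def test_reads_chain_with_ligand_and_strips_additives(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(PDB_FIXTURE)
        records = read_structures(path)
        assert len(records) == 1
        rec = records[0]
        assert rec.ligand_id == "XYZ"
        assert len(rec.ligand_atoms) == 2
        resnames = {a.residue_name for a in rec.protein_atoms}
        assert "HOH" not in resnames and "SO4" not in resnames

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(PDB_FIXTURE)
        rec = read_structures(path)[0]
        ca = [a for a in rec.protein_atoms if a.name == "CA" and a.residue_id[1] == 1]
        assert len(ca) == 1
        assert ca[0].coords[0] == pytest.approx(12.5)  # occupancy 0.60 conformer

    def test_write_read_round_trip(self, tmp_path, rng):
        base = {
            1: [("N", rng.uniform(-5, 5, 3)), ("CA", rng.uniform(-5, 5, 3))],
            2: [("CA", rng.uniform(-5, 5, 3))],
        }
        s = structure("toy", base, [("C1", "C", (0.25, -1.5, 3.125))])
        write_structure(s, tmp_path / "s.pdb")
        back = read_structures(tmp_path / "s.pdb")[0]
        assert len(back.protein_atoms) == len(s.protein_atoms)
        assert len(back.ligand_atoms) == 1
        for a, b in zip(s.protein_atoms, back.protein_atoms):
            assert np.allclose(a.coords, b.coords, atol=1e-3)


class TestSuperposeEnsemble:
    def test_recovers_common_frame(self, rng):
        base = {
            n + 1: [("CA", rng.uniform(-4, 4, 3)), ("CB", rng.uniform(-4, 4, 3))]
            for n in range(5)
        }
        lig = [("C1", "C", (0, 0, 0))]
        ref = structure("ref", base, lig)
        moved = []
        for sid in ("m1", "m2"):
            Q = random_rotation(rng)
            t = rng.uniform(-30, 30, 3)
            rot_base = {
                num: [(n, Q @ np.asarray(x) + t) for n, x in atoms]
                for num, atoms in base.items()
            }
            moved.append(
                structure(sid, rot_base, [("C1", "C", Q @ np.zeros(3) + t)])
            )
        structs = [ref] + moved
        site = consensus_site(structs, cutoff=8.0)
        aligned, ref_id = superpose_ensemble(structs, site)
        D = pairwise_rmsd_matrix(aligned, site)
        assert np.allclose(D.values, 0.0, atol=1e-8)
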