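"""Protein structures, binding sites, superposition and site RMSD matrices.

A :class:`StructureRecord` is one protein chain plus its co-crystallized
ligand.  The binding site of a chain is the set of residues with any heavy
atom within a distance cutoff (default 5.0 Å) of any ligand heavy atom.
Conformational similarity between chains is measured as the heavy-atom RMSD
over binding-site residues after all chains have been superposed onto a
common reference frame; the pairwise matrix of those RMSDs feeds the
clustering stage.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

ResidueId = tuple[str, int, str]  # (chain id, residue number, insertion code)

#: Waters, cryoprotectants, buffer components and common ions stripped on
#: read; they are irrelevant for ligand binding and must not be mistaken
#: for the reference ligand.
CRYSTALLOGRAPHIC_ADDITIVES = frozenset(
    {
        "HOH", "WAT", "DOD",
        "GOL", "EDO", "PEG", "PGE", "PG4", "MPD", "DMS", "BME", "IPA", "EOH",
        "ACT", "FMT", "CIT", "TRS", "EPE", "MES", "IMD",
        "SO4", "PO4", "NO3", "CO3",
        "NA", "K", "CL", "BR", "IOD", "F", "MG", "CA", "ZN", "MN", "FE",
        "FE2", "NI", "CU", "CO", "CD", "CS", "LI",
    }
)


class NoReferenceLigandError(ValueError):
    """The structure has no ligand heavy atoms to define a binding site."""


class DegenerateSuperpositionError(ValueError):
    """Fewer than 3 paired atoms, or a collinear pairing."""


@dataclass(eq=False)
class AtomRecord:
    """One atom: name, element, parent residue and Cartesian coordinates (Å)."""

    name: str
    element: str
    residue_id: ResidueId
    residue_name: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass(eq=False)
class StructureRecord:
    """One protein chain with its co-crystallized ligand atoms."""

    structure_id: str
    protein_atoms: list[AtomRecord]
    ligand_atoms: list[AtomRecord] = field(default_factory=list)
    ligand_id: str = ""

    def __post_init__(self) -> None:
        if not self.protein_atoms:
            raise ValueError(f"{self.structure_id}: structure has no protein atoms")

    def protein_heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.protein_atoms if a.is_heavy]

    def ligand_heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.ligand_atoms if a.is_heavy]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureRecord":
        """Return a copy with ``x -> R x + t`` applied to every atom."""

        def mv(atoms: list[AtomRecord]) -> list[AtomRecord]:
            return [
                replace(a, coords=rotation @ a.coords + translation) for a in atoms
            ]

        return StructureRecord(
            self.structure_id, mv(self.protein_atoms), mv(self.ligand_atoms), self.ligand_id
        )


@dataclass
class BindingSiteDefinition:
    """Residues of one chain within ``cutoff`` Å of its co-crystallized ligand."""

    structure_id: str
    member_residue_ids: set[ResidueId]
    cutoff: float = 5.0

    def to_jsonable(self) -> dict:
        return {
            "structure_id": self.structure_id,
            "cutoff": self.cutoff,
            "members": sorted(
                [list(r) for r in self.member_residue_ids], key=lambda r: (r[0], r[1], r[2])
            ),
        }


@dataclass
class DistanceMatrix:
    """Symmetric matrix of binding-site RMSDs (Å) over labelled structures."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match label count")
        self.validate()

    def validate(self) -> None:
        v = self.values
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix has non-finite entries")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-8):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(v < -1e-12):
            raise ValueError("distance matrix has negative entries")

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(["structure_id"] + self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(x) for x in parts[1:]])
        return cls(header, np.array(rows))


# ---------------------------------------------------------------------------
# PDB input


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved toward the lexicographically
    # smallest altloc so that unmarked/"A" conformers are preferred
    return max(atoms, key=lambda a: (a.occ, -ord(a.altloc or "A")))


def read_structures(
    path: str | Path, ligand_codes: dict[str, str] | None = None
) -> list[StructureRecord]:
    """Read a PDB file into one :class:`StructureRecord` per chain.

    Waters, buffer molecules and ions are stripped.  The co-crystallized
    ligand of a chain is the HETATM group named by ``ligand_codes`` (keyed
    by chain id), or, when not configured, the largest carbon-containing
    HETATM group in the chain.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    pdb_id = st.name.lower() if st.name else Path(path).stem
    records: list[StructureRecord] = []
    for model in st:
        for chain in model:
            protein: list[AtomRecord] = []
            het_groups: dict[tuple, list[AtomRecord]] = {}
            for res in chain:
                rid = (chain.name, res.seqid.num, res.seqid.icode.strip())
                resname = res.name.strip()
                # collapse alternate locations per atom name
                by_name: dict[str, list[gemmi.Atom]] = {}
                for atom in res:
                    by_name.setdefault(atom.name, []).append(atom)
                atoms = [
                    AtomRecord(
                        name=a.name,
                        element=a.element.name,
                        residue_id=rid,
                        residue_name=resname,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    )
                    for a in (_pick_altloc(group) for group in by_name.values())
                ]
                if res.het_flag == "H" or resname in CRYSTALLOGRAPHIC_ADDITIVES:
                    if resname in CRYSTALLOGRAPHIC_ADDITIVES:
                        continue
                    het_groups.setdefault((resname, rid), atoms)
                else:
                    protein.extend(atoms)
            if not protein:
                continue
            sid = f"{pdb_id}_{chain.name}"
            ligand_atoms: list[AtomRecord] = []
            ligand_id = ""
            wanted = (ligand_codes or {}).get(chain.name)
            candidates = {
                key: atoms
                for key, atoms in het_groups.items()
                if (wanted is None and any(a.element.upper() == "C" for a in atoms))
                or key[0] == wanted
            }
            if candidates:
                key = max(
                    candidates,
                    key=lambda k: (len([a for a in candidates[k] if a.is_heavy]), k),
                )
                ligand_atoms = candidates[key]
                ligand_id = key[0]
            records.append(StructureRecord(sid, protein, ligand_atoms, ligand_id))
        break  # first model only
    return records


def write_structure(record: StructureRecord, path: str | Path) -> None:
    """Write a StructureRecord as a minimal PDB file (ATOM + HETATM)."""
    lines = []
    serial = 1
    for kind, atoms in (("ATOM", record.protein_atoms), ("HETATM", record.ligand_atoms)):
        for a in atoms:
            chain, num, icode = a.residue_id
            x, y, z = a.coords
            lines.append(
                f"{kind:<6}{serial:>5} {a.name:<4}{a.residue_name:>4}"
                f" {chain[:1]}{num:>4}{icode or ' ':1}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Binding-site definition


def extract_binding_site(
    structure: StructureRecord, cutoff: float = 5.0
) -> BindingSiteDefinition:
    """Residues with any heavy atom within ``cutoff`` Å of a ligand heavy atom."""
    lig = structure.ligand_heavy_atoms()
    if not lig:
        raise NoReferenceLigandError(
            f"{structure.structure_id}: no reference ligand heavy atoms; "
            "cannot define a binding site"
        )
    lig_xyz = np.array([a.coords for a in lig])
    members: set[ResidueId] = set()
    prot = structure.protein_heavy_atoms()
    prot_xyz = np.array([a.coords for a in prot])
    dmin = cdist(prot_xyz, lig_xyz).min(axis=1)
    for atom, d in zip(prot, dmin):
        if d <= cutoff:
            members.add(atom.residue_id)
    return BindingSiteDefinition(structure.structure_id, members, cutoff)


def consensus_site(
    structures: list[StructureRecord], cutoff: float = 5.0
) -> set[ResidueId]:
    """Union of the per-structure binding sites across an ensemble.

    Site residues differ slightly between conformers; the union keeps every
    residue that contacts the ligand in at least one member, and per-pair
    RMSDs are later restricted to atoms resolved in both members.
    """
    out: set[ResidueId] = set()
    for s in structures:
        out |= extract_binding_site(s, cutoff).member_residue_ids
    return out


# ---------------------------------------------------------------------------
# Superposition (Kabsch) and RMSD


def kabsch(
    reference_xyz: np.ndarray, mobile_xyz: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` such that ``R @ x + t`` maps mobile coordinates
    into the reference frame, with ``det(R) = +1`` (proper rotation only).
    """
    ref = np.asarray(reference_xyz, float)
    mob = np.asarray(mobile_xyz, float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("paired coordinate arrays must both be (n, 3)")
    n = ref.shape[0]
    if n < 3:
        raise DegenerateSuperpositionError("need at least 3 atom pairs to superpose")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2 or np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise DegenerateSuperpositionError("collinear atom selection; superposition is degenerate")
    H = mob_c.T @ ref_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref.mean(axis=0) - R @ mob.mean(axis=0)
    fitted = (R @ mob.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return R, t, rmsd


def superpose(
    reference: StructureRecord,
    mobile: StructureRecord,
    atom_pairs: list[tuple[AtomRecord, AtomRecord]],
) -> tuple[StructureRecord, float]:
    """Rigid-fit ``mobile`` onto ``reference`` over explicit atom pairs.

    ``atom_pairs`` is a list of ``(reference atom, mobile atom)``.  Returns
    the transformed mobile structure and the fit RMSD in Å.
    """
    if len(atom_pairs) < 3:
        raise DegenerateSuperpositionError("need at least 3 atom pairs to superpose")
    ref_xyz = np.array([a.coords for a, _ in atom_pairs])
    mob_xyz = np.array([b.coords for _, b in atom_pairs])
    R, t, rmsd = kabsch(ref_xyz, mob_xyz)
    return mobile.transformed(R, t), rmsd


def _site_atom_map(
    structure: StructureRecord, site: set[ResidueId]
) -> dict[tuple[ResidueId, str], np.ndarray]:
    return {
        (a.residue_id, a.name): a.coords
        for a in structure.protein_heavy_atoms()
        if a.residue_id in site
    }


def match_site_atoms(
    reference: StructureRecord, mobile: StructureRecord, site: set[ResidueId]
) -> list[tuple[AtomRecord, AtomRecord]]:
    """Pair site heavy atoms of two chains by (residue id, atom name)."""
    ref_atoms = {
        (a.residue_id, a.name): a
        for a in reference.protein_heavy_atoms()
        if a.residue_id in site
    }
    pairs = []
    for b in mobile.protein_heavy_atoms():
        key = (b.residue_id, b.name)
        if b.residue_id in site and key in ref_atoms:
            pairs.append((ref_atoms[key], b))
    return pairs


def superpose_ensemble(
    structures: list[StructureRecord], site: set[ResidueId] | None = None, cutoff: float = 5.0
) -> tuple[list[StructureRecord], str]:
    """Superpose every chain onto a common reference over site heavy atoms.

    The reference is the chain with the most resolved site heavy atoms
    (ties broken by structure id).  Returns the transformed ensemble (the
    reference itself is returned unchanged) and the reference id.
    """
    if site is None:
        site = consensus_site(structures, cutoff)
    counts = {s.structure_id: len(_site_atom_map(s, site)) for s in structures}
    # most resolved site atoms; ties toward lexicographically smallest id
    best = max(counts.values())
    ref_id = min(k for k, v in counts.items() if v == best)
    reference = next(s for s in structures if s.structure_id == ref_id)
    out = []
    for s in structures:
        if s.structure_id == ref_id:
            out.append(s)
            continue
        pairs = match_site_atoms(reference, s, site)
        fitted, _ = superpose(reference, s, pairs)
        out.append(fitted)
    return out, ref_id


def pairwise_rmsd_matrix(
    structures: list[StructureRecord], site: set[ResidueId]
) -> DistanceMatrix:
    """Heavy-atom site RMSD for every pair of already-superposed chains.

    Each entry is computed over the site heavy atoms present (by residue id
    and atom name) in both members of the pair, in the shared frame, without
    per-pair re-fitting.
    """
    maps = [_site_atom_map(s, site) for s in structures]
    labels = [s.structure_id for s in structures]
    n = len(structures)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            common = maps[i].keys() & maps[j].keys()
            if not common:
                raise ValueError(
                    f"no common binding-site heavy atoms between "
                    f"{labels[i]} and {labels[j]}"
                )
            sq = [
                float(np.sum((maps[i][k] - maps[j][k]) ** 2)) for k in common
            ]
            values[i, j] = values[j, i] = math.sqrt(sum(sq) / len(sq))
    return DistanceMatrix(labels, values)


def write_binding_sites(sites: list[BindingSiteDefinition], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([s.to_jsonable() for s in sites], indent=2) + "\n"
    )
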