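"""Geometric protein–ligand interaction fingerprints on canonical positions.

Each fingerprint bit is a (canonical binding-site position, interaction
type) pair; the canonical positions follow the standard 85-position
kinase binding-site nomenclature (e.g. hinge.46, GK.45, aD.55) supplied
as a mapping table from (structure, residue) to position label.  Bits are
set from purely geometric criteria on heavy-atom coordinates:

* hydrogen bond: donor–acceptor heavy-atom distance ≤ 3.5 Å, with a
  D–H···A angle ≥ 120° required only when an explicit hydrogen is
  present on the donor (poses usually carry no hydrogens);
* hydrophobic contact: apolar carbon–carbon distance ≤ 4.5 Å;
* aromatic interaction: ring-centroid distance ≤ 5.5 Å;
* ionic interaction: opposite formal charges within 4.0 Å (charged atoms
  participate only in the ionic bit, so a salt bridge is not double-counted
  as a hydrogen bond).

All thresholds are configurable via :class:`InteractionCriteria`.  Donor /
acceptor / charge typing of protein atoms comes from a small built-in
per-residue table; ligand typing uses elements plus supplied formal
charges and ring definitions — there is deliberately no general chemical
perception engine here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from kinsel.structures import AtomRecord, ResidueId, StructureRecord

logger = logging.getLogger(__name__)

HBOND_DONOR = "hbond-donor"        # protein donates the hydrogen
HBOND_ACCEPTOR = "hbond-acceptor"  # protein accepts the hydrogen
HYDROPHOBIC = "hydrophobic"
AROMATIC = "aromatic"
IONIC = "ionic"
INTERACTION_TYPES = (HBOND_DONOR, HBOND_ACCEPTOR, HYDROPHOBIC, AROMATIC, IONIC)

UNMAPPED = "unmapped"

Bit = tuple[str, str]  # (position label, interaction type)


@dataclass
class InteractionCriteria:
    """Geometric thresholds for fingerprint bits (Å, degrees)."""

    hbond_distance: float = 3.5
    hbond_angle: float = 120.0
    hydrophobic_distance: float = 4.5
    aromatic_distance: float = 5.5
    ionic_distance: float = 4.0

    def as_dict(self) -> dict:
        return self.__dict__.copy()


# ---------------------------------------------------------------------------
# Atom typing (built-in table, no perception engine)

_SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "TRP": {"NE1"},
}
_SIDECHAIN_ACCEPTORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "ASN": {"OD1"}, "GLN": {"OE1"}, "HIS": {"ND1", "NE2"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
}
_CATIONIC = {"LYS": {"NZ"}, "ARG": {"NH1", "NH2", "NE"}, "HIS": set()}
_ANIONIC = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
#: side-chain carbons excluded from hydrophobic typing (carbonyl/carboxyl/
#: guanidinium carbons)
_POLAR_CARBONS = {
    "ASP": {"CG"}, "ASN": {"CG"}, "GLU": {"CD"}, "GLN": {"CD"}, "ARG": {"CZ"},
}
_AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


def _protein_is_donor(atom: AtomRecord) -> bool:
    if atom.name == "N":  # backbone amide
        return True
    return atom.name in _SIDECHAIN_DONORS.get(atom.residue_name, set())


def _protein_is_acceptor(atom: AtomRecord) -> bool:
    if atom.name == "O":  # backbone carbonyl
        return True
    return atom.name in _SIDECHAIN_ACCEPTORS.get(atom.residue_name, set())


def _protein_charge(atom: AtomRecord) -> int:
    if atom.name in _CATIONIC.get(atom.residue_name, set()):
        return 1
    if atom.name in _ANIONIC.get(atom.residue_name, set()):
        return -1
    return 0


def _protein_is_apolar_carbon(atom: AtomRecord) -> bool:
    if atom.element.upper() != "C" or atom.name in ("C", "CA"):
        return False
    return atom.name not in _POLAR_CARBONS.get(atom.residue_name, set())


# ---------------------------------------------------------------------------
# Ligand pose


@dataclass
class LigandPose:
    """Docked ligand coordinates plus the minimal typing metadata.

    ``formal_charges`` maps atom names to integer charges; ``rings`` lists
    aromatic rings as tuples of atom names.  Atoms with a non-zero formal
    charge take part in ionic bits only.
    """

    ligand_id: str
    atoms: list[AtomRecord]
    formal_charges: dict[str, int] = field(default_factory=dict)
    rings: list[tuple[str, ...]] = field(default_factory=list)
    conformer_id: str = ""

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]

    def charge(self, atom: AtomRecord) -> int:
        return self.formal_charges.get(atom.name, 0)

    def _bonded_hydrogens(self, atom: AtomRecord) -> list[AtomRecord]:
        hs = [a for a in self.atoms if not a.is_heavy]
        return [h for h in hs if np.linalg.norm(h.coords - atom.coords) <= 1.3]

    def ring_centroids(self) -> list[np.ndarray]:
        by_name = {a.name: a.coords for a in self.atoms}
        out = []
        for ring in self.rings:
            try:
                out.append(np.mean([by_name[n] for n in ring], axis=0))
            except KeyError as exc:
                raise ValueError(f"ring atom {exc} missing from pose") from exc
        return out


@dataclass(frozen=True)
class Fingerprint:
    """Set of interaction bits for one ligand pose on one conformer."""

    ligand_id: str
    conformer_id: str
    bits: frozenset[Bit]

    def has(self, position: str, itype: str) -> bool:
        return (position, itype) in self.bits


class PositionMap:
    """(structure, residue) → canonical binding-site position label."""

    def __init__(self, mapping: dict[tuple[str, ResidueId], str]):
        self.mapping = dict(mapping)
        # injectivity per structure: two residues must not share a label
        seen: dict[tuple[str, str], ResidueId] = {}
        for (sid, rid), label in self.mapping.items():
            key = (sid, label)
            if key in seen and seen[key] != rid:
                raise ValueError(
                    f"position map not injective for {sid}: label {label} "
                    f"assigned to {seen[key]} and {rid}"
                )
            seen[key] = rid

    def label(self, structure_id: str, residue_id: ResidueId) -> str | None:
        return self.mapping.get((structure_id, residue_id))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PositionMap":
        df = pd.read_csv(path, dtype={"icode": str}, keep_default_na=False)
        mapping = {}
        for r in df.itertuples():
            rid = (str(r.chain), int(r.resnum), str(r.icode or ""))
            mapping[(str(r.structure_id), rid)] = str(r.klifs_label)
        return cls(mapping)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "structure_id": sid, "chain": rid[0], "resnum": rid[1],
                "icode": rid[2], "klifs_label": label,
            }
            for (sid, rid), label in sorted(self.mapping.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Detection


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at b (degrees) of the a–b–c triple."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _hbond_geometry_ok(
    donor: AtomRecord,
    acceptor: AtomRecord,
    donor_hydrogens: list[AtomRecord],
    criteria: InteractionCriteria,
) -> bool:
    d = float(np.linalg.norm(donor.coords - acceptor.coords))
    if d > criteria.hbond_distance:
        return False
    if donor_hydrogens:
        return any(
            _angle(donor.coords, h.coords, acceptor.coords) >= criteria.hbond_angle
            for h in donor_hydrogens
        )
    return True  # distance-only when no explicit hydrogen is available


def detect_interactions(
    pose: LigandPose,
    protein: StructureRecord,
    position_map: PositionMap,
    criteria: InteractionCriteria | None = None,
) -> Fingerprint:
    """Geometric fingerprint of one ligand pose against one conformer.

    The pose and the protein must live in the same coordinate frame.  A
    contact at a residue absent from the position map is recorded under the
    sentinel label ``unmapped`` and warned about, never silently dropped.
    """
    criteria = criteria or InteractionCriteria()
    bits: set[Bit] = set()
    lig_heavy = pose.heavy_atoms()
    if not lig_heavy:
        raise ValueError(f"pose {pose.ligand_id}: no ligand heavy atoms")

    # ligand typing
    lig_n_o = [
        a for a in lig_heavy
        if a.element.upper() in ("N", "O", "S") and pose.charge(a) == 0
    ]
    lig_xyz = np.array([a.coords for a in lig_heavy])
    lig_apolar_c = []
    for a in lig_heavy:
        if a.element.upper() != "C":
            continue
        # a carbon bonded to a heteroatom is treated as polar
        near_het = any(
            o.element.upper() in ("N", "O") and
            np.linalg.norm(o.coords - a.coords) <= 1.7
            for o in lig_heavy if o is not a
        )
        if not near_het:
            lig_apolar_c.append(a)
    lig_charged = [(a, pose.charge(a)) for a in lig_heavy if pose.charge(a) != 0]
    lig_ring_centroids = pose.ring_centroids()

    residues: dict[ResidueId, list[AtomRecord]] = {}
    for a in protein.protein_heavy_atoms():
        residues.setdefault(a.residue_id, []).append(a)

    def add(residue_id: ResidueId, itype: str) -> None:
        label = position_map.label(protein.structure_id, residue_id)
        if label is None:
            warnings.warn(
                f"{protein.structure_id}: contact at unmapped residue "
                f"{residue_id}; recorded under '{UNMAPPED}'",
                stacklevel=3,
            )
            label = UNMAPPED
        bits.add((label, itype))

    for rid, atoms in residues.items():
        res_xyz = np.array([a.coords for a in atoms])
        if cdist(res_xyz, lig_xyz).min() > max(
            criteria.hbond_distance, criteria.hydrophobic_distance,
            criteria.aromatic_distance, criteria.ionic_distance,
        ):
            continue
        # hydrogen bonds: protein donor → ligand acceptor
        for p in atoms:
            if _protein_is_donor(p) and _protein_charge(p) == 0:
                for l in lig_n_o:
                    if _hbond_geometry_ok(p, l, [], criteria):
                        add(rid, HBOND_DONOR)
                        break
                else:
                    continue
                break
        # hydrogen bonds: ligand donor → protein acceptor
        for p in atoms:
            if _protein_is_acceptor(p) and _protein_charge(p) == 0:
                hit = False
                for l in lig_n_o:
                    hs = pose._bonded_hydrogens(l)
                    if _hbond_geometry_ok(l, p, hs, criteria):
                        hit = True
                        break
                if hit:
                    add(rid, HBOND_ACCEPTOR)
                    break
        # hydrophobic
        prot_c = [a for a in atoms if _protein_is_apolar_carbon(a)]
        if prot_c and lig_apolar_c:
            pc = np.array([a.coords for a in prot_c])
            lc = np.array([a.coords for a in lig_apolar_c])
            if cdist(pc, lc).min() <= criteria.hydrophobic_distance:
                add(rid, HYDROPHOBIC)
        # aromatic
        resname = atoms[0].residue_name
        ring_names = _AROMATIC_RINGS.get(resname)
        if ring_names and lig_ring_centroids:
            by_name = {a.name: a.coords for a in atoms}
            ring_atoms = [by_name[n] for n in ring_names if n in by_name]
            if len(ring_atoms) >= 5:
                centroid = np.mean(ring_atoms, axis=0)
                if any(
                    np.linalg.norm(centroid - c) <= criteria.aromatic_distance
                    for c in lig_ring_centroids
                ):
                    add(rid, AROMATIC)
        # ionic
        if lig_charged:
            for p in atoms:
                q = _protein_charge(p)
                if q == 0:
                    continue
                if any(
                    q * ql < 0
                    and np.linalg.norm(p.coords - l.coords) <= criteria.ionic_distance
                    for l, ql in lig_charged
                ):
                    add(rid, IONIC)
                    break
    return Fingerprint(pose.ligand_id, pose.conformer_id, frozenset(bits))


HINGE_BITS = ("hinge.46", "hinge.48")


def hinge_motif(fp: Fingerprint) -> bool:
    """True iff hydrogen-bond bits are present at both hinge.46 and hinge.48.

    The two backbone hydrogen bonds at those hinge positions anchor the
    heterocyclic core of ATP-competitive inhibitors.
    """
    return all(
        fp.has(pos, HBOND_DONOR) or fp.has(pos, HBOND_ACCEPTOR)
        for pos in HINGE_BITS
    )


# ---------------------------------------------------------------------------
# Enrichment and pose consistency


def fingerprint_matrix(fps: list[Fingerprint]) -> pd.DataFrame:
    """Ligands × bits 0/1 matrix; bit columns named ``position:type``."""
    all_bits = sorted({b for fp in fps for b in fp.bits})
    data = {
        f"{pos}:{typ}": [int((pos, typ) in fp.bits) for fp in fps]
        for pos, typ in all_bits
    }
    return pd.DataFrame(data, index=pd.Index([fp.ligand_id for fp in fps], name="ligand_id"))


def bit_enrichment(fps: list[Fingerprint], labels: dict[str, str]) -> pd.DataFrame:
    """Per-bit active/inactive frequency comparison.

    For every bit: frequency among actives and inactives, their difference,
    two-sided Fisher exact p, and Benjamini–Hochberg q.  Rows are sorted by
    |difference| descending.  ``labels`` maps ligand id to active/inactive.
    """
    lab = np.array([labels[fp.ligand_id] for fp in fps])
    n_act = int((lab == "active").sum())
    n_inact = int((lab == "inactive").sum())
    if n_act == 0 or n_inact == 0:
        raise ValueError("need at least one active and one inactive fingerprint")
    mat = fingerprint_matrix(fps)
    rows = []
    for col in mat.columns:
        present = mat[col].to_numpy().astype(bool)
        a = int((present & (lab == "active")).sum())
        i = int((present & (lab == "inactive")).sum())
        _, p = stats.fisher_exact([[a, n_act - a], [i, n_inact - i]])
        rows.append(
            {
                "bit": col,
                "freq_active": a / n_act,
                "freq_inactive": i / n_inact,
                "difference": a / n_act - i / n_inact,
                "fisher_p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["q_bh"] = _benjamini_hochberg(df["fisher_p"].to_numpy())
    return df.reindex(
        df["difference"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest p downwards
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def pose_consistency(
    poses: list[np.ndarray], threshold: float = 2.0
) -> tuple[float, bool]:
    """Mean pairwise heavy-atom RMSD over a ligand's per-conformer poses.

    Poses share the common superposition frame, so no re-fitting is done.
    A ligand is pose-stable when the mean is below ``threshold`` (default
    2.0 Å).
    """
    if len(poses) < 2:
        raise ValueError("need at least 2 poses for consistency statistics")
    arrays = [np.asarray(p, float) for p in poses]
    n_atoms = {a.shape for a in arrays}
    if len(n_atoms) > 1:
        raise ValueError(f"pose atom-count mismatch: {sorted(n_atoms)}")
    rmsds = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            d2 = np.sum((arrays[i] - arrays[j]) ** 2, axis=1)
            rmsds.append(float(np.sqrt(np.mean(d2))))
    mean = float(np.mean(rmsds))
    return mean, mean < threshold
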