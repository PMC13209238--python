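"""Seeded synthetic fixtures with known ground truth for every stage.

Three generators stand in for the inputs a real campaign would draw from
structure and bioactivity databases and a docking engine:

* :func:`gen_conformer_ensemble` — binding-site conformer ensembles with a
  planted cluster partition (cluster centres separated on the σ_between
  scale, members jittered at σ_within per atom);
* :func:`gen_screen_table` — dual-kinase docking score tables with a
  planted activity effect (actives shifted δ score units lower than
  inactives at noise σ) and a planted kinase-A bias (−β) for a tagged
  ligand subset, plus vdW/electrostatic components as fixed fractions of
  the total;
* :func:`gen_complex` — toy protein–ligand complexes whose coordinates
  satisfy exactly a requested set of interaction bits with ≥ 0.3 Å margin,
  surrounded by decoy atoms that violate every criterion by ≥ 0.3 Å.

Every generator is a pure function of its spec (seed included): an
identical spec yields identical output.  Scores are lower-is-better
throughout, the docking convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from kinsel.plif import (
    AROMATIC,
    HBOND_ACCEPTOR,
    HBOND_DONOR,
    HYDROPHOBIC,
    IONIC,
    Bit,
    InteractionCriteria,
    LigandPose,
    PositionMap,
)
from kinsel.structures import AtomRecord, StructureRecord

#: geometric safety margin (Å): planted contacts sit this far inside their
#: criterion, decoys this far outside every criterion
MARGIN = 0.3


# ---------------------------------------------------------------------------
# Conformer ensembles


@dataclass
class EnsembleSpec:
    k: int = 5
    members_per_cluster: int = 8
    n_residues: int = 20
    sigma_within: float = 0.3
    sigma_between: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_within <= 0 or self.sigma_between <= 0:
            raise ValueError("noise scales must be positive")


_RESIDUE_ATOMS = ("N", "CA", "C", "O", "CB")


def gen_conformer_ensemble(
    spec: EnsembleSpec,
) -> tuple[list[StructureRecord], dict[str, int]]:
    """Conformer ensemble with a planted cluster partition.

    A base binding site of ``n_residues`` five-atom residues is laid out at
    random; each cluster displaces every atom by an independent Gaussian of
    scale σ_between, and each member adds per-atom noise of scale σ_within.
    Every structure also carries a small co-crystallized ligand at the site
    centre so binding-site extraction works on the fixtures.  Returns the
    structures and the ground-truth partition (structure id → cluster).
    """
    rng = np.random.default_rng(spec.seed)
    n_atoms = spec.n_residues * len(_RESIDUE_ATOMS)
    base = rng.uniform(-8.0, 8.0, size=(spec.n_residues, 3))
    base_atoms = np.repeat(base, len(_RESIDUE_ATOMS), axis=0)
    base_atoms = base_atoms + rng.normal(0.0, 0.8, size=(n_atoms, 3))
    centre = base.mean(axis=0)

    structures: list[StructureRecord] = []
    partition: dict[str, int] = {}
    for c in range(spec.k):
        displacement = rng.normal(0.0, spec.sigma_between, size=(n_atoms, 3))
        cluster_atoms = base_atoms + displacement
        for m in range(spec.members_per_cluster):
            xyz = cluster_atoms + rng.normal(0.0, spec.sigma_within, size=(n_atoms, 3))
            atoms = []
            for r in range(spec.n_residues):
                rid = ("A", r + 1, "")
                for a, name in enumerate(_RESIDUE_ATOMS):
                    atoms.append(
                        AtomRecord(
                            name=name,
                            element=name[0],
                            residue_id=rid,
                            residue_name="ALA",
                            coords=xyz[r * len(_RESIDUE_ATOMS) + a],
                        )
                    )
            ligand = [
                AtomRecord("C1", "C", ("A", 900, ""), "LIG", centre + (0.0, 0.0, 0.0)),
                AtomRecord("C2", "C", ("A", 900, ""), "LIG", centre + (1.4, 0.0, 0.0)),
                AtomRecord("N1", "N", ("A", 900, ""), "LIG", centre + (0.0, 1.4, 0.0)),
            ]
            sid = f"ens_c{c + 1}_m{m + 1:02d}"
            structures.append(StructureRecord(sid, atoms, ligand, "LIG"))
            partition[sid] = c + 1
    return structures, partition


# ---------------------------------------------------------------------------
# Screen tables


@dataclass
class ScreenSpec:
    n_actives: int = 300
    n_inactives: int = 300
    delta: float = 1.0       # active score shift (score units; lower = better)
    sigma: float = 1.0       # score noise
    n_conformers: int = 3
    biased_fraction: float = 0.2  # fraction of actives tagged as kinase-A-biased
    beta: float = 0.0        # extra kinase-A shift of the tagged subset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0 or self.sigma <= 0 or self.beta < 0:
            raise ValueError("delta, beta must be >= 0 and sigma > 0")
        if not 0 <= self.biased_fraction <= 1:
            raise ValueError("biased_fraction must be in [0, 1]")


#: fixed component fractions of the total score used for the synthetic
#: decomposition (a real engine's decomposition is engine-internal)
VDW_FRACTION = 0.6
ELEC_FRACTION = 0.2
COMPONENT_NOISE = 0.25


def gen_screen_table(
    spec: ScreenSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dual-kinase score tables with a planted activity and bias structure.

    Per ligand and kinase a base total score is drawn: Normal(0, σ) for
    inactives, Normal(−δ, σ) for actives, with an extra −β on kinase A for
    the tagged subset of actives.  Each conformer replicate adds
    independent Normal(0, σ/2) jitter.  vdW and electrostatic components
    are fixed fractions of the total plus noise.  Returns the long-format
    score table (both kinases) and the ground-truth ligand table
    (ligand_id, label, biased, plus the ligand-level base score per kinase,
    i.e. the score before conformer jitter).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_actives + spec.n_inactives
    width = len(str(n))
    ligand_ids = [f"lig{str(i + 1).zfill(width)}" for i in range(n)]
    labels = np.array(["active"] * spec.n_actives + ["inactive"] * spec.n_inactives)
    n_biased = int(round(spec.biased_fraction * spec.n_actives))
    biased = np.zeros(n, dtype=bool)
    if n_biased:
        biased[rng.choice(spec.n_actives, size=n_biased, replace=False)] = True

    truth = pd.DataFrame({"ligand_id": ligand_ids, "label": labels, "biased": biased})

    rows = []
    for kinase in ("kinaseA", "kinaseB"):
        mean = np.where(labels == "active", -spec.delta, 0.0)
        if kinase == "kinaseA":
            mean = mean - np.where(biased, spec.beta, 0.0)
        base = rng.normal(mean, spec.sigma)
        truth[f"base_{kinase}"] = base
        for conf in range(spec.n_conformers):
            total = base + rng.normal(0.0, spec.sigma / 2.0, size=n)
            vdw = VDW_FRACTION * total + rng.normal(0.0, COMPONENT_NOISE, size=n)
            elec = ELEC_FRACTION * total + rng.normal(0.0, COMPONENT_NOISE, size=n)
            rows.append(
                pd.DataFrame(
                    {
                        "ligand_id": ligand_ids,
                        "conformer_id": f"{kinase}_conf{conf + 1}",
                        "kinase_id": kinase,
                        "total": total,
                        "vdw": vdw,
                        "elec": elec,
                    }
                )
            )
    scores = pd.concat(rows, ignore_index=True)
    return scores, truth


# ---------------------------------------------------------------------------
# Toy complexes with planted interactions


@dataclass
class ComplexSpec:
    planted: list[Bit] = field(default_factory=list)
    n_decoys: int = 0
    seed: int = 0
    criteria: InteractionCriteria = field(default_factory=InteractionCriteria)


@dataclass
class SyntheticComplex:
    protein: StructureRecord
    pose: LigandPose
    position_map: PositionMap
    planted_bits: frozenset[Bit]


#: distance (Å) between adjacent planted interaction sites on the layout
#: circle; large enough that sites cannot cross-talk under any criterion
_SITE_SPACING = 14.0


def _planted_geometry(
    itype: str, criteria: InteractionCriteria
) -> tuple[str, list[tuple[str, str, float]], list[tuple[str, str, float, int]]]:
    """Residue name, protein atoms and ligand atoms realizing one bit.

    Protein atoms are (name, element, signed offset along the outward site
    axis, 0 at the interaction atom); ligand atoms are (name, element,
    inward distance from the interaction atom, formal charge).
    """
    if itype == HBOND_ACCEPTOR:  # protein backbone O accepts from a ligand N
        d = criteria.hbond_distance - 2 * MARGIN
        return "GLY", [("O", "O", 0.0), ("C", "C", 1.3), ("CA", "C", 2.6), ("N", "N", 3.9)], [
            ("N", "N", d, 0)
        ]
    if itype == HBOND_DONOR:  # protein backbone N donates to a ligand O
        d = criteria.hbond_distance - 2 * MARGIN
        return "GLY", [("N", "N", 0.0), ("CA", "C", 1.5), ("C", "C", 3.0), ("O", "O", 4.2)], [
            ("O", "O", d, 0)
        ]
    if itype == HYDROPHOBIC:  # leucine side-chain carbon near a ligand carbon
        d = criteria.hydrophobic_distance - 2 * MARGIN
        return "LEU", [
            ("CD1", "C", 0.0), ("CG", "C", 1.5), ("CB", "C", 3.0),
            ("CA", "C", 4.5), ("C", "C", 6.0), ("N", "N", 7.5), ("O", "O", 9.0),
        ], [("C", "C", d, 0)]
    if itype == IONIC:  # lysine ammonium near a ligand carboxylate oxygen
        d = criteria.ionic_distance - 2 * MARGIN
        return "LYS", [
            ("NZ", "N", 0.0), ("CE", "C", 1.5), ("CD", "C", 3.0), ("CG", "C", 4.5),
            ("CB", "C", 6.0), ("CA", "C", 7.5), ("C", "C", 9.0),
            ("N", "N", 10.5), ("O", "O", 12.0),
        ], [("O", "O", d, -1)]
    raise ValueError(f"cannot plant interaction type {itype}")


def gen_complex(spec: ComplexSpec) -> SyntheticComplex:
    """Toy complex whose fingerprint equals the planted bit set exactly.

    Each planted (position, type) bit is realized by one residue placed on
    a wide circle, with the matching ligand atom offset inward so the
    geometry satisfies its criterion with at least a 0.3 Å margin while
    staying outside every other criterion.  Decoy protein atoms (alanines)
    are placed at least 0.3 Å beyond the largest cutoff from every ligand
    atom.  Duplicate (position, type) requests and geometrically infeasible
    requests raise before any coordinates are emitted.
    """
    crit = spec.criteria
    if len(set(spec.planted)) != len(spec.planted):
        raise ValueError("duplicate planted bits requested")
    by_position: dict[str, list[str]] = {}
    for pos, itype in spec.planted:
        by_position.setdefault(pos, []).append(itype)
    for pos, types in by_position.items():
        if len(types) > 1:
            # one residue per canonical position: multiple bit types at one
            # position would interfere geometrically
            raise ValueError(
                f"cannot plant multiple interaction types at position {pos}"
            )

    rng = np.random.default_rng(spec.seed)
    n_sites = max(len(spec.planted), 1)
    radius = max(_SITE_SPACING * n_sites / (2 * math.pi), _SITE_SPACING)

    protein_atoms: list[AtomRecord] = []
    ligand_atoms: list[AtomRecord] = []
    charges: dict[str, int] = {}
    rings: list[tuple[str, ...]] = []
    mapping: dict[tuple[str, tuple], str] = {}
    planted_bits: set[Bit] = set()
    structure_id = "synthetic_complex"

    for i, (pos, itype) in enumerate(spec.planted):
        theta = 2 * math.pi * i / n_sites
        u = np.array([math.cos(theta), math.sin(theta), 0.0])  # outward axis
        anchor = radius * u
        rid = ("A", i + 1, "")
        if itype == AROMATIC:
            # parallel stacked six-rings: centroid separation inside the
            # aromatic cutoff, all atom pairs outside the hydrophobic cutoff
            sep = crit.aromatic_distance - MARGIN
            if sep <= crit.hydrophobic_distance + MARGIN:
                raise ValueError("aromatic criterion too close to hydrophobic cutoff")
            ring_r = 1.39
            normal = u
            e1 = np.array([-math.sin(theta), math.cos(theta), 0.0])
            e2 = np.array([0.0, 0.0, 1.0])
            names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
            for k, name in enumerate(names):
                ang = 2 * math.pi * k / 6
                protein_atoms.append(
                    AtomRecord(
                        name, "C", rid, "PHE",
                        anchor + ring_r * (math.cos(ang) * e1 + math.sin(ang) * e2),
                    )
                )
            # minimal backbone, pointing outward
            for name, elem, off in (("CB", "C", 2.0), ("CA", "C", 3.5), ("C", "C", 5.0),
                                    ("N", "N", 6.5), ("O", "O", 8.0)):
                protein_atoms.append(AtomRecord(name, elem, rid, "PHE", anchor + off * u))
            lig_names = []
            for k in range(6):
                ang = 2 * math.pi * k / 6
                name = f"C{len(ligand_atoms) + 1}"
                lig_names.append(name)
                ligand_atoms.append(
                    AtomRecord(
                        name, "C", ("A", 900, ""), "LIG",
                        anchor - sep * normal
                        + ring_r * (math.cos(ang) * e1 + math.sin(ang) * e2),
                    )
                )
            rings.append(tuple(lig_names))
        else:
            resname, patoms, latoms = _planted_geometry(itype, crit)
            for name, elem, off in patoms:
                protein_atoms.append(AtomRecord(name, elem, rid, resname, anchor + off * u))
            for name, elem, dist, charge in latoms:
                aname = f"{name}{len(ligand_atoms) + 1}"
                ligand_atoms.append(
                    AtomRecord(aname, elem, ("A", 900, ""), "LIG", anchor - dist * u)
                )
                if charge:
                    charges[aname] = charge
        mapping[(structure_id, rid)] = pos
        planted_bits.add((pos, itype))

    if not ligand_atoms:
        # an inert ligand atom so fingerprints of bit-free complexes are defined
        ligand_atoms.append(AtomRecord("C1", "C", ("A", 900, ""), "LIG", np.zeros(3)))

    # decoy protein atoms: alanine CB carbons beyond every cutoff from every
    # ligand atom (and mapped, so they never trigger the unmapped warning)
    max_cut = max(
        crit.hbond_distance, crit.hydrophobic_distance,
        crit.aromatic_distance, crit.ionic_distance,
    )
    lig_xyz = np.array([a.coords for a in ligand_atoms])
    placed = 0
    attempts = 0
    while placed < spec.n_decoys:
        attempts += 1
        if attempts > 100 * max(spec.n_decoys, 1):
            raise ValueError("could not place decoy atoms outside all cutoffs")
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        point = (radius + max_cut + MARGIN + 4.0 + 8.0 * rng.random()) * direction
        if np.min(np.linalg.norm(lig_xyz - point, axis=1)) < max_cut + MARGIN:
            continue
        rid = ("D", placed + 1, "")
        protein_atoms.append(AtomRecord("CB", "C", rid, "ALA", point))
        mapping[(structure_id, rid)] = f"decoy.{placed + 1}"
        placed += 1

    protein = StructureRecord(structure_id, protein_atoms, [], "")
    pose = LigandPose("synthetic_ligand", ligand_atoms, charges, rings)
    return SyntheticComplex(protein, pose, PositionMap(mapping), frozenset(planted_bits))
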