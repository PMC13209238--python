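import numpy as np
import pytest

from kinsel.structures import AtomRecord, StructureRecord


def atom(name, element, rid, coords, resname="ALA"):
    return AtomRecord(
        name=name, element=element, residue_id=rid, residue_name=resname,
        coords=np.asarray(coords, float),
    )


def structure(sid, protein_coords, ligand_coords=(), chain="A"):
    """Build a StructureRecord from per-residue coordinate lists.

    ``protein_coords`` maps residue number -> list of (atom name, xyz);
    ``ligand_coords`` is a list of (atom name, element, xyz).
    """
    prot = [
        atom(name, name[0], (chain, num, ""), xyz)
        for num, atoms in protein_coords.items()
        for name, xyz in atoms
    ]
    lig = [
        atom(name, element, (chain, 900, ""), xyz, resname="LIG")
        for name, element, xyz in ligand_coords
    ]
    return StructureRecord(sid, prot, lig, "LIG" if lig else "")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_rotation(rng):
    """Uniform-ish proper rotation matrix from a random QR decomposition."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
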