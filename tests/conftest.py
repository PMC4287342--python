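"""Shared fixtures: hand-written PDB snippets and planted-cage structures."""

import numpy as np
import pytest

from cagescan.detect import DetectionParams
from cagescan.structure import Atom, Residue, Structure
from cagescan.synth import CageFixtureSpec, build_cage_fixture

MINIMAL_PDB = (
    "ATOM      1  CB  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
    "END\n"
)

ALTLOC_PDB = (
    "ATOM      1  CB AALA A   1       1.000   0.000   0.000  0.60  0.00           C\n"
    "ATOM      2  CB BALA A   1       9.000   0.000   0.000  0.40  0.00           C\n"
    "END\n"
)

TWO_MODEL_PDB = (
    "MODEL        1\n"
    "ATOM      1  CB  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
    "ENDMDL\n"
    "MODEL        2\n"
    "ATOM      1  CB  ALA A   1       5.000   0.000   0.000  1.00  0.00           C\n"
    "ENDMDL\n"
    "END\n"
)


def make_residue(name, atoms_spec, chain="A", seq=1):
    """Residue from [(atom_name, element, (x, y, z)), ...]."""
    atoms = [Atom(serial=i + 1, name=an, element=el, coords=np.array(xyz, float))
             for i, (an, el, xyz) in enumerate(atoms_spec)]
    return Residue(name=name, chain_id=chain, seq_num=seq, atoms=atoms)


def hexagon_ring(names, radius=1.39, center=(0.0, 0.0, 0.0), element="C"):
    """Planar hexagonal ring coordinates in z=center_z, adjacency order."""
    cx, cy, cz = center
    out = []
    for k, n in enumerate(names):
        ang = np.pi / 3 * k
        out.append((n, element, (cx + radius * np.cos(ang),
                                 cy + radius * np.sin(ang), cz)))
    return out


def make_phe(chain="A", seq=1, center=(0.0, 0.0, 0.0), cb_offset=(2.9, 0.0, 0.0)):
    ring = hexagon_ring(["CG", "CD1", "CE1", "CZ", "CE2", "CD2"], center=center)
    cb = tuple(np.array(center) + np.array(cb_offset))
    return make_residue("PHE", ring + [("CB", "C", cb)], chain=chain, seq=seq)


def rigid_transform(structure: Structure, rotation: np.ndarray,
                    translation: np.ndarray) -> Structure:
    models = []
    for residues in structure.models:
        moved = []
        for r in residues:
            moved.append(Residue(
                name=r.name, chain_id=r.chain_id, seq_num=r.seq_num,
                insertion_code=r.insertion_code,
                atoms=[a.moved(rotation @ a.coords + translation) for a in r.atoms]))
        models.append(moved)
    return Structure(pdb_id=structure.pdb_id, models=models)


@pytest.fixture
def params():
    return DetectionParams()


@pytest.fixture
def planted_fixture():
    return build_cage_fixture(CageFixtureSpec(
        n_residues=3, residue_types=("PHE", "TYR", "TRP"), ring_radius=5.0,
        normal_tilt=20.0, ligand_template="glutarimide", seed=5))
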