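"""Geometric kernel for aromatic-cage criteria.

Implements the three primitives the detection criteria are built from:

* ``side_chain_mass_center`` -- MC_SC, the mass centre of one residue's
  side-chain heavy atoms;
* ``cage_center`` -- MC_ALL, the mass centre of all side-chain heavy atoms
  of a residue set (the cage centre; ligand atoms never contribute);
* ``ring_normal`` / ``normal_center_angle`` -- the best-fit plane normal of
  the aromatic ring and its unsigned angle to the vector MC_SC -> MC_ALL.

Normals are axial (sign-free): the angle criterion uses min(theta, 180-theta),
so every angle reported here lies in [0, 90] degrees.  Mass weighting uses
standard atomic masses; a ``mass_weighted=False`` switch gives the plain
centroid for comparison.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .structure import Residue

__all__ = [
    "RING_ATOMS",
    "AROMATIC_RESIDUES",
    "side_chain_mass_center",
    "ring_normal",
    "cage_center",
    "normal_center_angle",
]

#: Ring atoms defining the aromatic plane.  TRP uses all nine indole atoms:
#: for a planar indole the fitted normal is indistinguishable from either
#: single ring's.
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

AROMATIC_RESIDUES = frozenset(RING_ATOMS)


def _weights(atoms, mass_weighted: bool) -> np.ndarray:
    if mass_weighted:
        return np.array([a.mass for a in atoms], float)
    return np.ones(len(atoms), float)


def side_chain_mass_center(r: Residue, mass_weighted: bool = True) -> np.ndarray:
    """MC_SC: mass-weighted mean of the residue's side-chain heavy atoms."""
    atoms = r.side_chain_atoms()
    if not atoms:
        raise ValueError(
            f"residue {r.name} {r.chain_id}{r.seq_num} has no side-chain heavy atoms"
        )
    w = _weights(atoms, mass_weighted)
    xyz = np.array([a.coords for a in atoms], float)
    return w @ xyz / w.sum()


def cage_center(residues: Iterable[Residue], mass_weighted: bool = True) -> np.ndarray:
    """MC_ALL: mass centre over the union of side-chain heavy atoms of a set."""
    atoms = [a for r in residues for a in r.side_chain_atoms()]
    if not atoms:
        raise ValueError("cage_center: empty residue set (or no side-chain atoms)")
    w = _weights(atoms, mass_weighted)
    xyz = np.array([a.coords for a in atoms], float)
    return w @ xyz / w.sum()


def ring_normal(r: Residue) -> np.ndarray:
    """Unit normal of the least-squares plane through the aromatic ring atoms.

    The smallest-singular-value direction of the centred ring-coordinate
    matrix.  The sign is arbitrary (axial convention); callers must not rely
    on it.  Raises for non-aromatic residues or missing ring atoms.
    """
    if r.name not in RING_ATOMS:
        raise ValueError(f"residue {r.name} {r.chain_id}{r.seq_num} is not Phe/Tyr/Trp")
    names = RING_ATOMS[r.name]
    missing = [n for n in names if all(a.name != n for a in r.atoms)]
    if missing:
        raise ValueError(
            f"residue {r.name} {r.chain_id}{r.seq_num}: missing ring atoms {missing}"
        )
    xyz = r.coords(names)
    xyz = xyz - xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(xyz, full_matrices=True)
    n = vt[-1]
    return n / np.linalg.norm(n)


def normal_center_angle(r: Residue, mc_all: np.ndarray,
                        mass_weighted: bool = True) -> float:
    """Unsigned angle (degrees, [0, 90]) between the ring normal and v.

    v is the vector from the residue's MC_SC to the cage centre MC_ALL.
    With axial normals the angle is min(theta, 180-theta), i.e. flipping the
    normal's sign cannot change the result.
    """
    v = np.asarray(mc_all, float) - side_chain_mass_center(r, mass_weighted)
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise ValueError(
            f"residue {r.name} {r.chain_id}{r.seq_num}: cage centre coincides with MC_SC"
        )
    n = ring_normal(r)
    cosang = abs(float(np.dot(n, v / nv)))
    return float(np.degrees(np.arccos(min(1.0, cosang))))
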