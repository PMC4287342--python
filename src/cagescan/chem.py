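"""Ligand bond inference, ring perception and moiety classification.

PDB HETATM groups carry no connectivity or formal charges, so bonds are
inferred from interatomic distances against covalent radii, rings from a
minimum cycle basis, and cations topologically.  The bound moiety -- the
part of the ligand inserted into the cage -- is the set of ligand atoms
near the cage centre MC_ALL, expanded to complete rings (with their
immediate substituents) when a ring atom is hit.

Five categories mirror the classes seen in cage-binding-site surveys:
heterocyclic rings, hydrocarbon rings, hydrocarbon chains with and without
N/O/S, and ammonium-based cations (methylated lysines, quaternary amines,
guanidinium groups).  The ladder gives cations precedence: a
trimethyllysine side chain is both an N-containing chain and a cation, and
belongs with the cations.
"""

from __future__ import annotations

import itertools
import warnings
from enum import Enum

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .detect import Cage
from .structure import Atom, LigandInstance

__all__ = [
    "COVALENT_RADII",
    "BOND_TOLERANCE",
    "LigandCategory",
    "infer_bonds",
    "find_rings",
    "moiety_atoms",
    "classify_ligand",
]

#: Single-bond covalent radii (A) for elements common in PDB ligands.
COVALENT_RADII: dict[str, float] = {
    "H": 0.37, "D": 0.37, "B": 0.82, "C": 0.77, "N": 0.75, "O": 0.73,
    "F": 0.71, "SI": 1.11, "P": 1.06, "S": 1.02, "CL": 0.99, "AS": 1.19,
    "SE": 1.16, "BR": 1.14, "I": 1.33,
}

BOND_TOLERANCE = 0.45  # A added to the radius sum


class LigandCategory(Enum):
    HETEROCYCLIC_RING = "heterocyclic_ring"
    HYDROCARBON_RING = "hydrocarbon_ring"
    HYDROCARBON_CHAIN = "hydrocarbon_chain"
    HYDROCARBON_CHAIN_NOS = "hydrocarbon_chain_nos"
    AMMONIUM_CATION = "ammonium_cation"
    UNCLASSIFIED = "unclassified"


def _radius(el: str) -> float:
    r = COVALENT_RADII.get(el.upper())
    if r is None:
        import gemmi

        g = gemmi.Element(el)
        if g.name == "X" or g.covalent_r <= 0:
            raise ValueError(f"unknown element {el!r}: no covalent radius")
        r = float(g.covalent_r)
    return r


def infer_bonds(atoms: list[Atom] | tuple[Atom, ...],
                tolerance: float = BOND_TOLERANCE) -> nx.Graph:
    """Covalent bond graph over heavy atoms (nodes are indices into ``atoms``).

    Two atoms are bonded when their distance is below the sum of covalent
    radii plus ``tolerance``.  Node attribute ``element`` carries the
    element symbol; ``atom`` the Atom itself.
    """
    if not atoms:
        raise ValueError("infer_bonds: empty atom list")
    g = nx.Graph()
    for i, a in enumerate(atoms):
        _radius(a.element)  # raises for unknown elements
        g.add_node(i, element=a.element.upper(), atom=a)
    if len(atoms) > 1:
        xyz = np.array([a.coords for a in atoms], float)
        d = squareform(pdist(xyz))
        for i, j in itertools.combinations(range(len(atoms)), 2):
            if 0.4 < d[i, j] < _radius(atoms[i].element) + _radius(atoms[j].element) + tolerance:
                g.add_edge(i, j)
    return g


def find_rings(g: nx.Graph) -> list[frozenset[int]]:
    """Smallest set of smallest rings, as atom-index sets, ordered
    deterministically by (size, sorted members)."""
    rings = [frozenset(cyc) for cyc in nx.minimum_cycle_basis(g)]
    return sorted(rings, key=lambda r: (len(r), sorted(r)))


def moiety_atoms(lig: LigandInstance, cage: Cage, g: nx.Graph | None = None,
                 radius: float = 4.0) -> set[int]:
    """Ligand atoms forming the cage-bound moiety (indices into lig.atoms).

    Seeds are the atoms within ``radius`` of MC_ALL (wider than the 3.0-A
    contact criterion so the inserted group is captured whole).  When a seed
    lies in a ring, the complete ring plus its directly bonded substituents
    join the moiety; acyclic seeds are taken as-is, so a chain dangling into
    the cage is classified by what actually inserts.
    """
    if g is None:
        g = infer_bonds(list(lig.atoms))
    d = np.linalg.norm(lig.coords() - np.asarray(cage.mc_all, float), axis=1)
    seeds = {i for i, x in enumerate(d) if x < radius}
    if not seeds:
        return set()
    moiety = set(seeds)
    for ring in find_rings(g):
        if ring & seeds:
            moiety |= ring
            for i in ring:
                moiety |= set(g.neighbors(i))
    return moiety


def _is_cation(g: nx.Graph, moiety: set[int]) -> bool:
    """Topological ammonium/guanidinium test on the moiety.

    N with >= 3 carbon neighbours (tri/tetra-substituted amine, e.g.
    trimethyllysine) or a guanidinium carbon (C bonded to three N).
    """
    for i in moiety:
        el = g.nodes[i]["element"]
        nbr_els = [g.nodes[j]["element"] for j in g.neighbors(i)]
        if el == "N" and sum(e == "C" for e in nbr_els) >= 3:
            return True
        if el == "C" and sum(e == "N" for e in nbr_els) >= 3:
            return True
    return False


def classify_ligand(lig: LigandInstance, cage: Cage,
                    moiety_radius: float = 4.0) -> LigandCategory:
    """Assign the cage-bound moiety to one of the five categories.

    Decision ladder (first match wins):

    1. cationic nitrogen centre in the moiety        -> AMMONIUM_CATION
    2. moiety atom in a ring with an N/O/S member    -> HETEROCYCLIC_RING
    3. moiety atom in an all-carbon ring             -> HYDROCARBON_RING
    4. acyclic moiety containing N/O/S               -> HYDROCARBON_CHAIN_NOS
    5. acyclic all-carbon moiety                     -> HYDROCARBON_CHAIN
    6. anything else (empty moiety, exotic elements) -> UNCLASSIFIED
    """
    g = infer_bonds(list(lig.atoms))
    moiety = moiety_atoms(lig, cage, g, moiety_radius)
    if not moiety:
        warnings.warn(
            f"ligand {lig.comp_id} {lig.chain_id}{lig.seq_num}: no atoms within "
            f"{moiety_radius} A of the cage centre; unclassified",
            stacklevel=2,
        )
        return LigandCategory.UNCLASSIFIED
    if _is_cation(g, moiety):
        return LigandCategory.AMMONIUM_CATION
    rings = [r for r in find_rings(g) if r & moiety]
    if rings:
        for ring in rings:
            if any(g.nodes[i]["element"] in ("N", "O", "S") for i in ring):
                return LigandCategory.HETEROCYCLIC_RING
        if any(all(g.nodes[i]["element"] == "C" for i in ring) for ring in rings):
            return LigandCategory.HYDROCARBON_RING
    elements = {g.nodes[i]["element"] for i in moiety}
    if elements & {"N", "O", "S"}:
        return LigandCategory.HYDROCARBON_CHAIN_NOS
    if elements == {"C"}:
        return LigandCategory.HYDROCARBON_CHAIN
    return LigandCategory.UNCLASSIFIED
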