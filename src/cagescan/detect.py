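"""Detection of ligand-binding aromatic cage-like conformations.

A set of at least three Phe/Tyr/Trp residues from one polypeptide chain is a
cage-like conformation around a ligand when

a) every pairwise distance between their side-chain mass centres (MC_SC) is
   less than ``pair_center_max`` (default 10.0 A);
b) for at least three of the residues, the angle between the aromatic-ring
   normal and the vector from the residue's MC_SC to the set's overall
   side-chain mass centre (MC_ALL) is less than ``angle_max`` (default 60
   degrees); and
c) at least ``min_ligand_atoms_in_center`` ligand heavy atoms (default 2)
   lie within ``center_contact_max`` (default 3.0 A) of MC_ALL.

Only aromatic residues with a heavy atom within ``ligand_contact_max``
(default 6.0 A) of a ligand heavy atom are considered at all.

Threshold comparisons are strict ("less than").  Because MC_ALL depends on
the residue set, a maximal clique under (a) can fail (b)/(c) while one of
its sub-cliques passes; ``detect_cages`` therefore descends from maximal
cliques into sub-cliques and reports the inclusion-maximal accepted sets.
The literal all-subsets enumeration is available as ``mode="all-subsets"``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .geometry import AROMATIC_RESIDUES, cage_center, normal_center_angle
from .geometry import side_chain_mass_center
from .structure import LigandInstance, Residue, Structure

__all__ = [
    "DetectionParams",
    "Cage",
    "cage_key",
    "candidate_residues",
    "enumerate_candidate_sets",
    "evaluate_cage",
    "detect_cages",
    "deduplicate",
    "group_by_ligand",
]


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds of the geometric criteria (defaults: the published scan).

    ``boundary_eps_dist`` / ``boundary_eps_deg`` implement strict "<" for
    floating-point inputs: a value within the guard of the cutoff counts as
    at the cutoff and is rejected.  The guards are far below coordinate
    precision (PDB files carry 1e-3 A).
    """

    ligand_contact_max: float = 6.0     # A, criterion gate: residue near ligand
    pair_center_max: float = 10.0       # A, criterion (a)
    angle_max: float = 60.0             # degrees, criterion (b)
    center_contact_max: float = 3.0     # A, criterion (c)
    min_residues: int = 3
    min_ligand_atoms_in_center: int = 2
    mass_weighted: bool = True
    boundary_eps_dist: float = 1e-9     # A
    boundary_eps_deg: float = 1e-5      # degrees

    def __post_init__(self):
        for name in ("ligand_contact_max", "pair_center_max", "angle_max",
                     "center_contact_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_residues < 1 or self.min_ligand_atoms_in_center < 1:
            raise ValueError("minimum counts must be >= 1")


def _lt(x: float, cutoff: float, eps: float) -> bool:
    return x < cutoff - eps


@dataclass(frozen=True)
class Cage:
    """An accepted cage-like conformation around one ligand."""

    pdb_id: str
    ligand: LigandInstance
    residues: tuple[Residue, ...]           # sorted by (seq_num, icode, name)
    chain_id: str
    mc_all: np.ndarray
    angles_deg: dict[tuple, float]          # residue.id -> angle
    n_ligand_atoms_in_center: int
    n_angle_satisfying: int

    @property
    def residue_ids(self) -> tuple[tuple, ...]:
        return tuple(r.id for r in self.residues)

    def residue_labels(self) -> tuple[str, ...]:
        """Human-readable labels like ('TRP79', 'TRP85', ...)."""
        return tuple(f"{r.name}{r.seq_num}{r.insertion_code}" for r in self.residues)


def cage_key(c: Cage) -> tuple:
    """Identity for deduplication: composite residue names+numbers, plus ligand.

    Two cages are redundant when the sorted (name, number) composition of
    their residue sets matches and they bind the same chemical component.
    """
    comp = tuple(sorted((r.name, r.seq_num) for r in c.residues))
    return (c.ligand.comp_id, comp)


def candidate_residues(s: Structure, lig: LigandInstance, p: DetectionParams,
                       model_index: int = 0) -> list[Residue]:
    """Aromatic polymer residues with a heavy atom near a ligand heavy atom.

    "Near" is a minimum heavy-atom to heavy-atom distance strictly below
    ``ligand_contact_max``.  The ligand's own residue group is never a
    candidate.
    """
    lig_xyz = lig.coords()
    out = []
    for res in s.residues(model_index):
        if res.name not in AROMATIC_RESIDUES or res.is_hetatm:
            continue
        if (res.chain_id, res.seq_num, res.insertion_code) == (
                lig.chain_id, lig.seq_num, lig.insertion_code):
            continue
        heavy = res.heavy_atoms()
        if not heavy:
            continue
        xyz = np.array([a.coords for a in heavy], float)
        dmin = float(cdist(xyz, lig_xyz).min())
        if _lt(dmin, p.ligand_contact_max, p.boundary_eps_dist):
            out.append(res)
    return out


def _pair_graph(residues: list[Residue], p: DetectionParams) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(residues)))
    mc = [side_chain_mass_center(r, p.mass_weighted) for r in residues]
    for i, j in itertools.combinations(range(len(residues)), 2):
        d = float(np.linalg.norm(mc[i] - mc[j]))
        if _lt(d, p.pair_center_max, p.boundary_eps_dist):
            g.add_edge(i, j)
    return g


def _sort_set(cand: list[Residue]) -> tuple[Residue, ...]:
    return tuple(sorted(cand, key=lambda r: (r.seq_num, r.insertion_code, r.name)))


def enumerate_candidate_sets(residues: list[Residue],
                             p: DetectionParams | None = None) -> list[tuple[Residue, ...]]:
    """Maximal cliques (size >= ``min_residues``) of the MC_SC-distance graph.

    Residues are grouped by chain first: cages never span chains.  Cliques
    are returned deterministically ordered (chain, then residue numbers).
    """
    p = p or DetectionParams()
    by_chain: dict[str, list[Residue]] = {}
    for r in residues:
        by_chain.setdefault(r.chain_id, []).append(r)
    out: list[tuple[Residue, ...]] = []
    for chain in sorted(by_chain):
        rs = by_chain[chain]
        g = _pair_graph(rs, p)
        for clique in nx.find_cliques(g):
            if len(clique) >= p.min_residues:
                out.append(_sort_set([rs[i] for i in clique]))
    out.sort(key=lambda t: (t[0].chain_id,) + tuple(r.seq_num for r in t))
    return out


def evaluate_cage(cand: tuple[Residue, ...] | list[Residue], lig: LigandInstance,
                  p: DetectionParams | None = None,
                  pdb_id: str = "XXXX") -> Cage | None:
    """Apply criteria (b) and (c) to one candidate set; None on rejection.

    The candidate set is assumed to satisfy (a) (it came from
    ``enumerate_candidate_sets``).  All members are kept in the returned
    cage, each annotated with its normal-to-centre angle; acceptance needs
    only three satisfying residues.
    """
    p = p or DetectionParams()
    cand = _sort_set(list(cand))
    if len(cand) < p.min_residues:
        return None
    mc_all = cage_center(cand, p.mass_weighted)
    angles = {r.id: normal_center_angle(r, mc_all, p.mass_weighted) for r in cand}
    n_ok = sum(_lt(a, p.angle_max, p.boundary_eps_deg) for a in angles.values())
    if n_ok < 3:
        return None
    d = np.linalg.norm(lig.coords() - mc_all, axis=1)
    n_center = int(np.sum([_lt(float(x), p.center_contact_max, p.boundary_eps_dist)
                           for x in d]))
    if n_center < p.min_ligand_atoms_in_center:
        return None
    return Cage(
        pdb_id=pdb_id,
        ligand=lig,
        residues=cand,
        chain_id=cand[0].chain_id,
        mc_all=mc_all,
        angles_deg=angles,
        n_ligand_atoms_in_center=n_center,
        n_angle_satisfying=n_ok,
    )


def _pairwise_ok(cand: tuple[Residue, ...], p: DetectionParams) -> bool:
    mc = [side_chain_mass_center(r, p.mass_weighted) for r in cand]
    return all(
        _lt(float(np.linalg.norm(mc[i] - mc[j])), p.pair_center_max, p.boundary_eps_dist)
        for i, j in itertools.combinations(range(len(cand)), 2)
    )


def _maximal_accepted(cliques: list[tuple[Residue, ...]], lig: LigandInstance,
                      p: DetectionParams, pdb_id: str) -> list[Cage]:
    """Descend from maximal cliques to inclusion-maximal accepted subsets."""
    accepted: list[Cage] = []
    accepted_sets: list[frozenset] = []
    seen: set[frozenset] = set()
    # process larger sets first so acceptance prunes their subsets
    frontier = sorted({frozenset(r.id for r in c): c for c in cliques}.items(),
                      key=lambda kv: -len(kv[0]))
    queue = [(k, tuple(v)) for k, v in frontier]
    while queue:
        queue.sort(key=lambda kv: -len(kv[0]))
        key, cand = queue.pop(0)
        if key in seen:
            continue
        seen.add(key)
        if any(key <= a for a in accepted_sets):
            continue
        cage = evaluate_cage(cand, lig, p, pdb_id)
        if cage is not None:
            accepted.append(cage)
            accepted_sets.append(key)
            continue
        if len(cand) > p.min_residues:
            for sub in itertools.combinations(cand, len(cand) - 1):
                sk = frozenset(r.id for r in sub)
                if sk not in seen:
                    queue.append((sk, sub))
    return accepted


def detect_cages(s: Structure, p: DetectionParams | None = None,
                 model_index: int = 0, mode: str = "maximal") -> list[Cage]:
    """End-to-end detection: every ligand, every chain, criteria (a)-(c).

    ``mode="maximal"`` (default) reports inclusion-maximal accepted residue
    sets derived from maximal cliques; ``mode="all-subsets"`` enumerates
    every subset of size >= ``min_residues`` literally (exponential; meant
    for small structures and oracle testing).  Output ordering is
    deterministic: (ligand id, chain, residue numbers).
    """
    from .structure import extract_ligands

    p = p or DetectionParams()
    if mode not in ("maximal", "all-subsets"):
        raise ValueError(f"unknown mode {mode!r}")
    cages: list[Cage] = []
    for lig in extract_ligands(s, model_index):
        cands = candidate_residues(s, lig, p, model_index)
        if mode == "maximal":
            cliques = enumerate_candidate_sets(cands, p)
            by_chain: dict[str, list] = {}
            for c in cliques:
                by_chain.setdefault(c[0].chain_id, []).append(c)
            for chain in sorted(by_chain):
                cages.extend(_maximal_accepted(by_chain[chain], lig, p, s.pdb_id))
        else:
            by_chain = {}
            for r in cands:
                by_chain.setdefault(r.chain_id, []).append(r)
            for chain in sorted(by_chain):
                rs = by_chain[chain]
                for k in range(p.min_residues, len(rs) + 1):
                    for sub in itertools.combinations(rs, k):
                        sub = _sort_set(list(sub))
                        if not _pairwise_ok(sub, p):
                            continue
                        cage = evaluate_cage(sub, lig, p, s.pdb_id)
                        if cage is not None:
                            cages.append(cage)
    cages.sort(key=lambda c: (c.ligand.id, c.chain_id,
                              tuple(r.seq_num for r in c.residues),
                              tuple(r.name for r in c.residues)))
    return cages


def deduplicate(cages: list[Cage]) -> list[Cage]:
    """Drop redundant cages: same composite residue names+numbers, same ligand.

    First occurrence wins; idempotent.  The key is per chemical component,
    so deduplication acts within each ligand group.
    """
    seen: set[tuple] = set()
    out: list[Cage] = []
    for c in cages:
        k = cage_key(c)
        if k not in seen:
            seen.add(k)
            out.append(c)
    return out


def group_by_ligand(cages: list[Cage]) -> dict[str, list[Cage]]:
    """Partition cages by the chemical component id of their ligand."""
    out: dict[str, list[Cage]] = {}
    for c in cages:
        out.setdefault(c.ligand.comp_id, []).append(c)
    return out
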