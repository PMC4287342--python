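"""Synthetic-structure generator: planted aromatic cages and ideal ligands.

Fixtures are built so that every detection criterion can be verified by
independent arithmetic on the emitted coordinates:

* side-chain mass centres (MC_SC) of the planted residues sit on a circle
  of configurable radius in the z=0 plane, so all pairwise MC_SC distances
  are chords known in closed form;
* the overall centre MC_ALL is the mass-weighted mean of the MC_SC targets
  (exactly, because MC_ALL of a union is the mass-weighted mean of the
  per-residue mass centres) and each ring is oriented so its plane normal
  makes *exactly* ``normal_tilt`` degrees with the vector MC_SC -> MC_ALL;
* the requested number of ligand atoms is placed within 1 A of MC_ALL.

Side chains use ideal internal geometry; backbone atoms are stubs placed
away from the cage so they cannot perturb any criterion (they enter no mass
centre and are farther from the ligand than the side chain).  The same seed
always yields byte-identical PDB output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structure import Atom, LigandInstance, Residue, Structure

__all__ = [
    "CageFixtureSpec",
    "CageFixture",
    "FixtureError",
    "LIGAND_TEMPLATES",
    "make_ligand",
    "make_cage_structure",
    "build_cage_fixture",
    "make_two_chain_structure",
    "make_random_structure",
    "fixture_sweep",
    "boundary_structures",
]


class FixtureError(ValueError):
    """Raised for geometrically impossible fixture specifications."""


# ---------------------------------------------------------------------------
# ligand templates (ideal coordinates, heavy atoms only)

_HEX = 1.39  # aromatic ring bond length -> hexagon circumradius equals it


def _hexagon(names_elements: list[tuple[str, str]]) -> list[tuple[str, str, tuple]]:
    out = []
    for k, (name, el) in enumerate(names_elements):
        ang = np.pi / 3 * k
        out.append((name, el, (_HEX * np.cos(ang), _HEX * np.sin(ang), 0.0)))
    return out


def _exocyclic(ring_xyz: tuple, bond: float) -> tuple:
    v = np.array(ring_xyz, float)
    u = v / np.linalg.norm(v[:2])  # radial, in-plane
    p = v + u * bond
    return (float(p[0]), float(p[1]), float(p[2]))


def _zigzag(names_elements: list[tuple[str, str]], bond: float = 1.53) -> list:
    half = np.radians(111.1) / 2
    dx, dy = bond * np.sin(half), bond * np.cos(half)
    out = []
    for k, (name, el) in enumerate(names_elements):
        out.append((name, el, (k * dx, (k % 2) * dy, 0.0)))
    return out


def _build_templates() -> dict:
    t: dict[str, dict] = {}

    benzene = _hexagon([(f"C{i+1}", "C") for i in range(6)])
    t["benzene"] = {"comp_id": "BNZ", "atoms": benzene, "center": ("C1", "C2")}

    tyr_ring = benzene + [("OH", "O", _exocyclic(benzene[3][2], 1.36))]
    t["tyrosine-ring"] = {"comp_id": "TYH", "atoms": tyr_ring, "center": ("C1", "C2")}

    glut = _hexagon([("N1", "N"), ("C2", "C"), ("C3", "C"),
                     ("C4", "C"), ("C5", "C"), ("C6", "C")])
    glut += [("O2", "O", _exocyclic(glut[1][2], 1.23)),
             ("O6", "O", _exocyclic(glut[5][2], 1.23))]
    t["glutarimide"] = {"comp_id": "GIM", "atoms": glut, "center": ("N1", "C2")}

    ura = _hexagon([("N1", "N"), ("C2", "C"), ("N3", "N"),
                    ("C4", "C"), ("C5", "C"), ("C6", "C")])
    ura += [("O2", "O", _exocyclic(ura[1][2], 1.23)),
            ("O4", "O", _exocyclic(ura[3][2], 1.23))]
    t["uracil"] = {"comp_id": "URA", "atoms": ura, "center": ("N1", "C2")}

    t["butane"] = {"comp_id": "BUT",
                   "atoms": _zigzag([(f"C{i+1}", "C") for i in range(4)]),
                   "center": ("C2", "C3")}

    leu = _zigzag([("CB", "C"), ("CG", "C"), ("CD1", "C")])
    cg = np.array(leu[1][2])
    leu.append(("CD2", "C", tuple(cg + np.array([0.0, 1.53, 0.0]))))
    t["leucine-sidechain"] = {"comp_id": "LSC", "atoms": leu, "center": ("CG", "CD1")}

    put = _zigzag([("N1", "N"), ("C2", "C"), ("C3", "C"),
                   ("C4", "C"), ("C5", "C"), ("N6", "N")], bond=1.50)
    t["putrescine"] = {"comp_id": "PUT", "atoms": put, "center": ("C3", "C4")}

    tet = 1.49 / np.sqrt(3.0)
    tma = [("N", "N", (0.0, 0.0, 0.0)),
           ("C1", "C", (tet, tet, tet)),
           ("C2", "C", (tet, -tet, -tet)),
           ("C3", "C", (-tet, tet, -tet))]
    t["trimethylammonium"] = {"comp_id": "TMA", "atoms": tma, "center": ("N", "C1")}

    m3l = list(tma) + [("CE", "C", (-tet, -tet, tet))]
    ce = np.array(m3l[-1][2])
    chain_dir = ce / np.linalg.norm(ce)
    pos = ce.copy()
    for k, name in enumerate(("CD", "CG", "CB")):
        step = chain_dir * 1.26 + np.array([0.0, 0.0, 0.85 * (-1) ** k])
        pos = pos + step / np.linalg.norm(step) * 1.53
        m3l.append((name, "C", tuple(pos)))
    t["trimethyllysine"] = {"comp_id": "M3L", "atoms": m3l, "center": ("N", "C1")}

    return t


#: name -> {"comp_id", "atoms": [(name, element, xyz)...], "center": (a, b)}
LIGAND_TEMPLATES = _build_templates()


def make_ligand(template_name: str, chain_id: str = "A", seq_num: int = 900,
                serial_start: int = 1) -> LigandInstance:
    """Idealised ligand of one template, at its template coordinates."""
    try:
        t = LIGAND_TEMPLATES[template_name]
    except KeyError:
        raise FixtureError(
            f"unknown ligand template {template_name!r}; "
            f"known: {sorted(LIGAND_TEMPLATES)}"
        ) from None
    atoms = tuple(
        Atom(serial=serial_start + i, name=n, element=el,
             coords=np.array(xyz, float), is_hetatm=True)
        for i, (n, el, xyz) in enumerate(t["atoms"])
    )
    return LigandInstance(comp_id=t["comp_id"], chain_id=chain_id,
                          seq_num=seq_num, insertion_code="", atoms=atoms)


# ---------------------------------------------------------------------------
# aromatic side-chain templates (local frame: ring plane z=0, CB side +x)

def _phe_sidechain() -> list[tuple[str, str, tuple]]:
    ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]  # adjacency order
    atoms = []
    for k, name in enumerate(ring_names):
        ang = np.pi / 3 * k
        atoms.append((name, "C", (_HEX * np.cos(ang), _HEX * np.sin(ang), 0.0)))
    atoms.append(("CB", "C", (_HEX + 1.51, 0.0, 0.0)))
    return atoms


def _tyr_sidechain() -> list:
    atoms = _phe_sidechain()
    cz = np.array(atoms[3][2])
    atoms.append(("OH", "O", tuple(cz + np.array([-1.36, 0.0, 0.0]))))
    return atoms


# planar idealised indole; all nine ring atoms in z=0
_TRP_RING = [
    ("CG", "C", (0.000, 0.000, 0.0)),
    ("CD1", "C", (1.093, 0.810, 0.0)),
    ("NE1", "N", (0.713, 2.110, 0.0)),
    ("CE2", "C", (-0.655, 2.097, 0.0)),
    ("CD2", "C", (-1.074, 0.780, 0.0)),
    ("CE3", "C", (-2.420, 0.403, 0.0)),
    ("CZ3", "C", (-3.395, 1.378, 0.0)),
    ("CH2", "C", (-3.030, 2.723, 0.0)),
    ("CZ2", "C", (-1.673, 3.075, 0.0)),
]


def _trp_sidechain() -> list:
    atoms = list(_TRP_RING)
    atoms.append(("CB", "C", (-0.018, -1.500, 0.0)))
    return atoms


_SIDECHAINS = {"PHE": _phe_sidechain, "TYR": _tyr_sidechain, "TRP": _trp_sidechain}

# backbone stubs, local frame: hang off the CB side, away from the ring
_BACKBONE_OFFSETS = [("CA", "C", (1.1, 1.1, 0.0)), ("N", "N", (2.2, 0.6, 0.0)),
                     ("C", "C", (1.3, 2.6, 0.0)), ("O", "O", (0.7, 3.6, 0.0))]


def _atom_mass(element: str) -> float:
    import gemmi

    return gemmi.Element(element).weight


def _template_residue(res_type: str) -> tuple[list, np.ndarray, float]:
    """(atoms, side-chain mass centre, side-chain mass) in the local frame."""
    try:
        sc = _SIDECHAINS[res_type]()
    except KeyError:
        raise FixtureError(f"residue type {res_type!r} not one of PHE/TYR/TRP") from None
    m = np.array([_atom_mass(el) for _, el, _ in sc])
    xyz = np.array([p for _, _, p in sc], float)
    c = m @ xyz / m.sum()
    cb = np.array(dict((n, p) for n, _, p in sc)["CB"], float)
    atoms = list(sc)
    for name, el, off in _BACKBONE_OFFSETS:
        atoms.append((name, el, tuple(cb + np.array(off))))
    return atoms, c, float(m.sum())


def _orientation(v_hat: np.ndarray, tilt_deg: float) -> np.ndarray:
    """Rotation mapping local +z (ring normal) to a direction at ``tilt_deg``
    from v_hat (tilting towards +z), and local +x (CB side) away from the
    cage centre."""
    z = np.array([0.0, 0.0, 1.0])
    tilt = np.radians(tilt_deg)
    n_t = np.cos(tilt) * v_hat + np.sin(tilt) * z
    n_t /= np.linalg.norm(n_t)
    b = -v_hat - (-v_hat @ n_t) * n_t
    if np.linalg.norm(b) < 1e-8:  # tilt 0: ring plane contains z; point CB up
        b = z - (z @ n_t) * n_t
    b /= np.linalg.norm(b)
    return np.column_stack([b, np.cross(n_t, b), n_t])


# ---------------------------------------------------------------------------
# fixture specification and assembly

@dataclass(frozen=True)
class CageFixtureSpec:
    """Recipe for one planted cage.

    ``ring_radius`` is the MC_SC distance from the cage axis; residues are
    evenly spaced on the circle.  ``normal_tilt`` is the exact angle between
    each ring normal and the vector to the cage centre.
    ``n_ligand_atoms_at_center``: for >= 2 the ligand is centred so that
    many atoms sit within 1 A of MC_ALL; for 1 it is displaced radially so
    that exactly one atom lies within the 3.0-A contact shell.
    """

    n_residues: int = 3
    residue_types: tuple[str, ...] = ("PHE", "PHE", "PHE")
    ring_radius: float = 5.0
    normal_tilt: float = 0.0
    ligand_template: str = "glutarimide"
    n_ligand_atoms_at_center: int = 2
    seed: int = 0
    chain_id: str = "A"

    def __post_init__(self):
        if self.n_residues < 1 or self.ring_radius <= 0:
            raise FixtureError("need n_residues >= 1 and ring_radius > 0")
        if not (0.0 <= self.normal_tilt <= 90.0):
            raise FixtureError("normal_tilt must be in [0, 90] degrees")
        if len(self.residue_types) != self.n_residues:
            raise FixtureError("residue_types length must equal n_residues")


@dataclass
class CageFixture:
    """A built fixture plus the closed-form geometry used to build it."""

    spec: CageFixtureSpec
    structure: Structure
    planted_ids: tuple[tuple, ...]          # residue .id tuples
    mc_sc: np.ndarray                        # (n, 3) targets
    mc_all: np.ndarray
    pair_distances: np.ndarray               # (n, n) closed-form chords
    tilt_deg: float
    n_center_atoms: int                      # ligand atoms within 3.0 A of MC_ALL
    min_contact: np.ndarray                  # per-residue min atom distance to ligand

    def expected_detectable(self, pair_max: float = 10.0, angle_max: float = 60.0,
                            contact_max: float = 6.0, center_max: float = 3.0,
                            min_residues: int = 3, min_center_atoms: int = 2,
                            guard: float = 1e-6) -> bool:
        """Whether the planted set satisfies every criterion, from the
        closed-form construction values (independent of the detector)."""
        n = len(self.planted_ids)
        iu = np.triu_indices(n, 1)
        return bool(
            n >= min_residues
            and np.all(self.pair_distances[iu] < pair_max - guard)
            and self.tilt_deg < angle_max - guard
            and np.all(self.min_contact < contact_max - guard)
            and self.n_center_atoms >= min_center_atoms
        )


def _place_ligand(spec: CageFixtureSpec, mc_all: np.ndarray,
                  rng: np.random.Generator,
                  protein_xyz: np.ndarray,
                  clash_cutoff: float) -> LigandInstance:
    lig = make_ligand(spec.ligand_template, chain_id=spec.chain_id, seq_num=900)
    t = LIGAND_TEMPLATES[spec.ligand_template]
    xyz0 = lig.coords()
    names = [a.name for a in lig.atoms]
    idx = [names.index(n) for n in t["center"]]

    best = None
    for _ in range(64):
        rot = Rotation.random(random_state=rng).as_matrix()
        xyz = xyz0 @ rot.T
        if spec.n_ligand_atoms_at_center >= 2:
            k = min(spec.n_ligand_atoms_at_center, len(idx))
            anchor = xyz[idx[:k]].mean(axis=0)
            xyz = xyz - anchor + mc_all
        else:
            # exactly one atom inside the 3.0-A contact shell: slide the
            # ligand radially outwards until only the innermost remains
            xyz = xyz - xyz[idx[0]]
            direction = np.array([1.0, 0.0, 0.0])
            for r0 in np.arange(2.0, 6.0, 0.05):
                cand = xyz + mc_all + direction * r0
                inside = np.sum(np.linalg.norm(cand - mc_all, axis=1) < 3.0 - 1e-6)
                if inside == 1:
                    xyz = cand
                    break
            else:
                continue
        dmin = float(cdist(xyz, protein_xyz).min())
        if best is None or dmin > best[0]:
            best = (dmin, xyz)
        if dmin >= clash_cutoff:
            break
    if best is None or best[0] < clash_cutoff:
        raise FixtureError(
            f"cannot place ligand {spec.ligand_template!r} without clashes "
            f"(min distance {0 if best is None else best[0]:.2f} A)"
        )
    xyz = best[1]
    atoms = tuple(a.moved(x) for a, x in zip(lig.atoms, xyz))
    return LigandInstance(lig.comp_id, lig.chain_id, lig.seq_num, "", atoms)


def _axis_rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    return Rotation.from_rotvec(axis * angle_rad).as_matrix()


def _place_residues(spec: CageFixtureSpec, targets: np.ndarray,
                    mc_all: np.ndarray, templates: list,
                    spin_deg: float) -> list[Residue]:
    """Residues at the MC_SC targets with exact normal tilt.

    ``spin_deg`` rotates each side chain about its own ring normal -- a free
    parameter that changes no criterion and is searched to avoid clashes.
    """
    residues: list[Residue] = []
    serial = 1
    for i, ((atoms, c_local, _), target) in enumerate(zip(templates, targets)):
        v = mc_all - target
        v_hat = v / np.linalg.norm(v)
        rot = _orientation(v_hat, spec.normal_tilt)
        n_t = rot[:, 2]
        rot = _axis_rotation(n_t, np.radians(spin_deg)) @ rot
        shift = target - rot @ c_local
        placed = []
        for name, el, xyz in atoms:
            placed.append(Atom(serial=serial, name=name, element=el,
                               coords=rot @ np.array(xyz, float) + shift))
            serial += 1
        residues.append(Residue(name=spec.residue_types[i], chain_id=spec.chain_id,
                                seq_num=10 * (i + 1), atoms=placed))
    return residues


def build_cage_fixture(spec: CageFixtureSpec, clash_cutoff: float = 0.9) -> CageFixture:
    """Assemble the fixture and record its closed-form geometry."""
    n = spec.n_residues
    azimuths = 2.0 * np.pi * np.arange(n) / n
    targets = spec.ring_radius * np.column_stack(
        [np.cos(azimuths), np.sin(azimuths), np.zeros(n)])

    templates = [_template_residue(t) for t in spec.residue_types]
    masses = np.array([m for _, _, m in templates])
    mc_all = masses @ targets / masses.sum()

    # search the free spin angle for a clash-free, roomy arrangement
    scored = []
    for spin in np.arange(0.0, 360.0, 30.0):
        residues = _place_residues(spec, targets, mc_all, templates, spin)
        d_rr = np.inf
        for i, j in itertools.combinations(range(n), 2):
            d_rr = min(d_rr, float(cdist(residues[i].coords(),
                                         residues[j].coords()).min()))
        side_xyz = np.vstack([np.array([a.coords for a in r.side_chain_atoms()])
                              for r in residues])
        d_center = float(np.linalg.norm(side_xyz - mc_all, axis=1).min())
        scored.append((min(d_rr, d_center), d_rr, spin, residues))
    scored.sort(key=lambda t: -t[0])

    rng = np.random.default_rng(spec.seed)
    residues = lig = None
    for _, d_rr, spin, res in scored:
        if d_rr < clash_cutoff:
            continue
        protein_xyz = np.vstack([r.coords() for r in res])
        try:
            lig = _place_ligand(spec, mc_all, rng, protein_xyz, clash_cutoff)
        except FixtureError:
            continue
        residues = res
        break
    if residues is None or lig is None:
        raise FixtureError(
            f"residue clash in fixture: cannot arrange {n} x "
            f"{'/'.join(spec.residue_types)} at radius {spec.ring_radius} A "
            f"without contacts below {clash_cutoff} A"
        )

    lig_res = Residue(name=lig.comp_id, chain_id=lig.chain_id, seq_num=lig.seq_num,
                      atoms=[a for a in lig.atoms])

    structure = Structure(pdb_id="FIXT", models=[residues + [lig_res]])

    lig_xyz = lig.coords()
    pair_d = cdist(targets, targets)
    min_contact = np.array([float(cdist(r.coords(), lig_xyz).min()) for r in residues])
    n_center = int(np.sum(np.linalg.norm(lig_xyz - mc_all, axis=1) < 3.0 - 1e-6))
    return CageFixture(
        spec=spec,
        structure=structure,
        planted_ids=tuple(r.id for r in residues),
        mc_sc=targets,
        mc_all=mc_all,
        pair_distances=pair_d,
        tilt_deg=spec.normal_tilt,
        n_center_atoms=n_center,
        min_contact=min_contact,
    )


def make_cage_structure(spec: CageFixtureSpec) -> Structure:
    """The Structure of :func:`build_cage_fixture` (same construction)."""
    return build_cage_fixture(spec).structure


def make_two_chain_structure(spec_a: CageFixtureSpec, spec_b: CageFixtureSpec,
                             separation: float = 40.0) -> Structure:
    """Two independent planted cages on chains A and B, well separated."""
    import dataclasses

    fa = build_cage_fixture(dataclasses.replace(spec_a, chain_id="A"))
    fb = build_cage_fixture(dataclasses.replace(spec_b, chain_id="B"))
    shift = np.array([separation, 0.0, 0.0])
    moved = []
    for res in fb.structure.models[0]:
        moved.append(Residue(name=res.name, chain_id="B", seq_num=res.seq_num,
                             insertion_code=res.insertion_code,
                             atoms=[a.moved(a.coords + shift) for a in res.atoms]))
    return Structure(pdb_id="FIX2", models=[fa.structure.models[0] + moved])


# ---------------------------------------------------------------------------
# sweeps, boundaries, randomised fixtures

_SWEEP_TYPES = ("PHE", "TYR", "TRP", "PHE", "TRP")


def fixture_sweep() -> list[CageFixtureSpec]:
    """The seeded 27-spec sweep: n in {3,4,5} x tilt in {0,30,59} deg x
    radius in {4,5,6} A.  Some combinations are geometrically incapable of
    satisfying the pairwise-distance criterion (the chord between evenly
    spaced residues exceeds 10 A); ``expected_detectable`` reports which."""
    specs = []
    seed = 0
    for n in (3, 4, 5):
        for tilt in (0.0, 30.0, 59.0):
            for radius in (4.0, 5.0, 6.0):
                specs.append(CageFixtureSpec(
                    n_residues=n, residue_types=_SWEEP_TYPES[:n],
                    ring_radius=radius, normal_tilt=tilt,
                    ligand_template="butane", n_ligand_atoms_at_center=2,
                    seed=seed))
                seed += 1
    return specs


def boundary_structures() -> dict[str, Structure]:
    """Fixtures pinned at each criterion's threshold; none may yield a cage.

    * ``tilt_60``: every ring normal at exactly 60 deg from v;
    * ``pair_10``: four residues whose diagonal MC_SC distances are exactly
      10.0 A (square of circumradius 5);
    * ``contact_6``: nearest ligand atom exactly 6.0 A below the lowest
      protein atom (identical x, y, so the distance is exact in floating
      point);
    * ``center_1``: only one ligand atom inside the 3.0-A shell around
      MC_ALL.
    """
    out: dict[str, Structure] = {}
    out["tilt_60"] = make_cage_structure(CageFixtureSpec(
        n_residues=3, residue_types=("PHE",) * 3, ring_radius=5.0,
        normal_tilt=60.0, ligand_template="butane", seed=1))
    out["pair_10"] = make_cage_structure(CageFixtureSpec(
        n_residues=4, residue_types=("PHE",) * 4, ring_radius=5.0,
        normal_tilt=0.0, ligand_template="butane", seed=2))

    base = build_cage_fixture(CageFixtureSpec(
        n_residues=3, residue_types=("PHE",) * 3, ring_radius=5.0,
        normal_tilt=0.0, ligand_template="butane", seed=3))
    residues = [r for r in base.structure.models[0] if r.name != "BUT"]
    prot = np.vstack([r.coords() for r in residues])
    low = prot[np.argmin(prot[:, 2])]
    lig = make_ligand("butane")
    xyz = lig.coords()
    # remap the zigzag (x, y, 0) -> (y, 0, -x): the chain extends straight
    # down in z, its first atom on top
    placed = np.column_stack([xyz[:, 1], np.zeros(len(xyz)), -xyz[:, 0]])
    placed = placed - placed[0] + np.array([low[0], low[1], low[2] - 6.0])
    atoms = [a.moved(x) for a, x in zip(lig.atoms, placed)]
    lig_res = Residue(name="BUT", chain_id="A", seq_num=900, atoms=atoms)
    out["contact_6"] = Structure(pdb_id="BND6", models=[residues + [lig_res]])

    out["center_1"] = make_cage_structure(CageFixtureSpec(
        n_residues=3, residue_types=("PHE",) * 3, ring_radius=5.0,
        normal_tilt=0.0, ligand_template="butane",
        n_ligand_atoms_at_center=1, seed=4))
    return out


def make_meander_trace(n_strands: int = 4, strand_len: int = 10,
                       strand_spacing: float = 4.8, rise: float = 3.4,
                       pleat: float = 0.6) -> np.ndarray:
    """Idealised C-alpha trace of one antiparallel beta-meander.

    ``n_strands`` strands of ``strand_len`` residues joined by single-residue
    turns; with the defaults the half is 43 residues, the size of one sheet
    of a small two-sheet beta-sandwich-like domain.
    """
    coords: list[np.ndarray] = []
    for k in range(n_strands):
        x = k * strand_spacing
        idx = range(strand_len) if k % 2 == 0 else range(strand_len - 1, -1, -1)
        for j, i in enumerate(idx):
            coords.append(np.array([x, rise * i, pleat * (-1.0) ** j]))
        if k < n_strands - 1:
            y_end = rise * (strand_len - 1) if k % 2 == 0 else 0.0
            turn_y = y_end + (2.5 if k % 2 == 0 else -2.5)
            coords.append(np.array([x + strand_spacing / 2, turn_y, 0.0]))
    return np.array(coords)


def make_symmetric_domain(noise: float = 0.0, seed: int = 0,
                          angle_deg: float = 180.0) -> tuple[np.ndarray, int]:
    """Synthetic two-half domain with exact internal two-fold symmetry.

    The second half is a rigid copy of the first (rotated ``angle_deg``
    about an offset axis, emulating two sheets packed against each other);
    optional Gaussian ``noise`` (A, per coordinate) perturbs the second
    half only.  Returns (coords, split_index): a perfectly symmetric domain
    superposes half onto half with RMSD 0 at register 0.
    """
    half = make_meander_trace()
    rot = Rotation.from_rotvec(np.radians(angle_deg) * np.array([0.0, 1.0, 0.0]))
    other = half @ rot.as_matrix().T + np.array([12.0, 0.0, 18.0])
    if noise > 0:
        rng = np.random.default_rng(seed)
        other = other + rng.normal(scale=noise, size=other.shape)
    return np.vstack([half, other]), len(half)


def make_homolog_pair(seed: int = 0, n: int = 100, noise: float = 0.3,
                      n_outliers: int = 5, displacement: float = 8.0
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair of traces related by a random rigid motion plus noise.

    ``n_outliers`` residues of the copy are additionally displaced by
    ``displacement`` A (a flexible loop), which iterative core trimming
    should exclude.  Returns (A, B, outlier_indices).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n) * 0.35
    A = np.column_stack([9.0 * np.cos(t), 9.0 * np.sin(t), 1.6 * t])
    A = A + rng.normal(scale=0.2, size=A.shape)
    R = Rotation.random(random_state=rng).as_matrix()
    shift = rng.uniform(-20, 20, size=3)
    B = A @ R.T + shift + rng.normal(scale=noise, size=A.shape)
    outliers = rng.choice(n, size=n_outliers, replace=False)
    for i in outliers:
        u = rng.normal(size=3)
        B[i] += displacement * u / np.linalg.norm(u)
    return A, B, np.sort(outliers)


def make_random_structure(seed: int, n_aromatic: int | None = None,
                          ligand_template: str = "butane") -> Structure:
    """Randomised small structure for oracle testing: one central ligand,
    3-12 aromatic residues at random positions/orientations on one chain.

    Positions are rejected on clashes, so detection input stays physical;
    everything is deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    if n_aromatic is None:
        n_aromatic = int(rng.integers(3, 13))
    lig = make_ligand(ligand_template)
    xyz = lig.coords()
    rot = Rotation.random(random_state=rng).as_matrix()
    xyz = (xyz - xyz.mean(axis=0)) @ rot.T
    lig_atoms = [a.moved(x) for a, x in zip(lig.atoms, xyz)]
    placed_xyz = [np.array([a.coords for a in lig_atoms])]

    residues: list[Residue] = []
    serial = 100
    types = ("PHE", "TYR", "TRP")
    for i in range(n_aromatic):
        res_type = types[int(rng.integers(0, 3))]
        atoms_t, c_local, _ = _template_residue(res_type)
        for _ in range(200):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            target = u * rng.uniform(3.0, 9.0)
            orient = Rotation.random(random_state=rng).as_matrix()
            shift = target - orient @ c_local
            coords = np.array([orient @ np.array(p, float) + shift
                               for _, _, p in atoms_t])
            if min(float(cdist(coords, q).min()) for q in placed_xyz) >= 1.5:
                break
        else:  # pragma: no cover - extremely unlikely at these densities
            raise FixtureError("could not place residue without clashes")
        placed_xyz.append(coords)
        atoms = []
        for (name, el, _), x in zip(atoms_t, coords):
            atoms.append(Atom(serial=serial, name=name, element=el, coords=x))
            serial += 1
        residues.append(Residue(name=res_type, chain_id="A",
                                seq_num=10 * (i + 1), atoms=atoms))
    lig_res = Residue(name=lig.comp_id, chain_id="A", seq_num=900, atoms=lig_atoms)
    return Structure(pdb_id=f"RND{seed % 1000:03d}", models=[residues + [lig_res]])
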