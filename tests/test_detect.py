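"""Cage detection: criteria, clique enumeration, dedup, oracle equivalence."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cagescan.detect import (Cage, DetectionParams, cage_key,
                             candidate_residues, deduplicate, detect_cages,
                             enumerate_candidate_sets, evaluate_cage,
                             group_by_ligand)
from cagescan.geometry import (cage_center, normal_center_angle,
                               side_chain_mass_center)
from cagescan.structure import (Atom, LigandInstance, Residue, Structure,
                                extract_ligands)
from cagescan.synth import (CageFixtureSpec, build_cage_fixture,
                            make_cage_structure, make_random_structure,
                            make_two_chain_structure)

from conftest import make_phe, make_residue, rigid_transform


def one_atom_ligand(xyz, comp="LIG", chain="A", seq=900):
    return LigandInstance(comp, chain, seq, "", (
        Atom(serial=999, name="C1", element="C", coords=np.array(xyz, float),
             is_hetatm=True),))


def structure_of(residues, ligand=None, pdb_id="TEST"):
    rows = list(residues)
    if ligand is not None:
        rows.append(Residue(name=ligand.comp_id, chain_id=ligand.chain_id,
                            seq_num=ligand.seq_num, atoms=list(ligand.atoms)))
    return Structure(pdb_id=pdb_id, models=[rows])


class TestCandidateResidues:
    @pytest.mark.parametrize("dz,included", [(5.9, True), (6.1, False),
                                             (6.0, False)])
    def test_contact_threshold_is_strict(self, dz, included, params):
        phe = make_phe(seq=1)
        nearest = min((a.coords for a in phe.atoms), key=lambda c: c[1])
        lig = one_atom_ligand(nearest - np.array([0.0, dz, 0.0]))
        s = structure_of([phe], lig)
        found = candidate_residues(s, lig, params)
        assert (len(found) == 1) == included

    @pytest.mark.parametrize("resname", ["LEU", "HIS", "ARG", "MET"])
    def test_only_phe_tyr_trp_considered(self, resname, params):
        res = make_residue(resname, [("CB", "C", (0, 0, 0)),
                                     ("CG", "C", (1.5, 0, 0))])
        lig = one_atom_ligand((0.0, 3.0, 0.0))
        assert candidate_residues(structure_of([res], lig), lig, params) == []

    def test_ligand_own_residue_never_candidate(self, params):
        # an aromatic HETATM group is a ligand, not a cage residue
        trp_het = make_residue("TYR", [("CB", "C", (0, 0, 0))], seq=900)
        trp_het.atoms = [Atom(1, "CB", "C", np.zeros(3), is_hetatm=True)]
        lig = extract_ligands(structure_of([trp_het]))[0]
        assert candidate_residues(structure_of([trp_het]), lig, params) == []


def lone_cb_phe(xyz, seq, chain="A"):
    """PHE with a single side-chain atom: MC_SC is exactly that point."""
    return make_residue("PHE", [("CB", "C", tuple(xyz))], chain=chain, seq=seq)


def brute_force_sets(residues, p):
    """Independent oracle: all subsets passing the all-pairs condition."""
    out = []
    for k in range(p.min_residues, len(residues) + 1):
        for sub in itertools.combinations(residues, k):
            mcs = [side_chain_mass_center(r) for r in sub]
            if all(np.linalg.norm(mcs[i] - mcs[j]) < p.pair_center_max
                   for i in range(k) for j in range(i + 1, k)):
                out.append(frozenset(r.seq_num for r in sub))
    return out


class TestEnumerateCandidateSets:
    def test_single_triangle(self, params):
        rs = [lone_cb_phe((0, 0, 0), 1), lone_cb_phe((8, 0, 0), 2),
              lone_cb_phe((4, 6, 0), 3)]
        (only,) = enumerate_candidate_sets(rs, params)
        assert {r.seq_num for r in only} == {1, 2, 3}

    def test_broken_pair_gives_two_triangles_matching_oracle(self, params):
        # 4 points, exactly one pair beyond the cutoff
        rs = [lone_cb_phe((0, 0, 0), 1), lone_cb_phe((7, 0, 0), 2),
              lone_cb_phe((3.5, 5, 0), 3), lone_cb_phe((3.5, -5.25, 0), 4)]
        d = np.linalg.norm(np.array([3.5, 5, 0]) - np.array([3.5, -5.25, 0]))
        assert d > params.pair_center_max
        sets = enumerate_candidate_sets(rs, params)
        got = {frozenset(r.seq_num for r in s) for s in sets}
        assert got == {frozenset({1, 2, 3}), frozenset({1, 2, 4})}
        # every brute-force-accepted subset is contained in a maximal set
        for sub in brute_force_sets(rs, params):
            assert any(sub <= g for g in got)

    def test_two_residues_no_sets(self, params):
        rs = [lone_cb_phe((0, 0, 0), 1), lone_cb_phe((5, 0, 0), 2)]
        assert enumerate_candidate_sets(rs, params) == []

    def test_pair_at_exactly_ten_not_connected(self, params):
        rs = [lone_cb_phe((0.0, 0.0, 0.0), 1), lone_cb_phe((10.0, 0.0, 0.0), 2),
              lone_cb_phe((5.0, 3.0, 0.0), 3)]
        assert enumerate_candidate_sets(rs, params) == []

    def test_chains_never_mix(self, params):
        rs = [lone_cb_phe((0, 0, 0), 1, "A"), lone_cb_phe((3, 0, 0), 2, "A"),
              lone_cb_phe((6, 0, 0), 3, "B")]
        assert enumerate_candidate_sets(rs, params) == []


def tilted_phe(target, towards, tilt_deg, seq):
    """PHE with MC_SC at ``target`` and ring normal at ``tilt_deg`` from the
    direction to ``towards`` -- built with independent arithmetic."""
    from cagescan.synth import _orientation, _template_residue

    atoms, c_local, _ = _template_residue("PHE")
    v = np.asarray(towards, float) - np.asarray(target, float)
    rot = _orientation(v / np.linalg.norm(v), tilt_deg)
    shift = np.asarray(target, float) - rot @ c_local
    placed = [(n, el, tuple(rot @ np.array(p) + shift)) for n, el, p in atoms]
    return make_residue("PHE", placed, seq=seq)


class TestEvaluateCage:
    def make_cage_input(self, tilts, radius=5.0):
        n = len(tilts)
        residues = []
        for i, tilt in enumerate(tilts):
            ang = 2 * np.pi * i / n
            target = radius * np.array([np.cos(ang), np.sin(ang), 0.0])
            residues.append(tilted_phe(target, (0, 0, 0), tilt, seq=10 * (i + 1)))
        center = cage_center(residues)
        lig = LigandInstance("LIG", "A", 900, "", (
            Atom(1, "C1", "C", center + np.array([0.4, 0, 0]), is_hetatm=True),
            Atom(2, "C2", "C", center - np.array([0.4, 0, 0]), is_hetatm=True)))
        return residues, lig

    def test_three_of_five_angles_suffice(self, params):
        residues, lig = self.make_cage_input([40, 50, 55, 70, 80])
        cage = evaluate_cage(residues, lig, params)
        assert cage is not None
        assert cage.n_angle_satisfying == 3
        assert len(cage.residues) == 5  # non-satisfying members kept

    def test_fewer_than_three_good_angles_rejected(self, params):
        residues, lig = self.make_cage_input([65, 70, 80, 40, 50])
        assert evaluate_cage(residues, lig, params) is None

    def test_one_center_atom_rejected(self, params):
        residues, _ = self.make_cage_input([10, 10, 10])
        center = cage_center(residues)
        lig = LigandInstance("LIG", "A", 900, "", (
            Atom(1, "C1", "C", center, is_hetatm=True),
            Atom(2, "C2", "C", center + np.array([4.5, 0, 0]), is_hetatm=True)))
        assert evaluate_cage(residues, lig, params) is None


class TestDetectCages:
    def test_planted_cage_recovered(self, planted_fixture):
        cages = detect_cages(planted_fixture.structure)
        assert len(cages) == 1
        assert set(cages[0].residue_ids) == set(planted_fixture.planted_ids)
        assert cages[0].n_ligand_atoms_in_center >= 2

    def test_no_hetatm_no_cages(self):
        s = structure_of([make_phe(seq=1)])
        assert detect_cages(s) == []

    def test_two_chains_two_cages(self):
        s = make_two_chain_structure(
            CageFixtureSpec(seed=1), CageFixtureSpec(seed=2))
        cages = detect_cages(s)
        assert len(cages) == 2
        assert sorted(c.chain_id for c in cages) == ["A", "B"]

    def test_rigid_motion_invariance(self, planted_fixture):
        rng = np.random.default_rng(3)
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-30, 30, 3)
        moved = rigid_transform(planted_fixture.structure, R, t)
        a = detect_cages(planted_fixture.structure)
        b = detect_cages(moved)
        assert [c.residue_ids for c in a] == [c.residue_ids for c in b]
        for ca, cb in zip(a, b):
            for key in ca.angles_deg:
                assert ca.angles_deg[key] == pytest.approx(
                    cb.angles_deg[key], abs=1e-7)


def brute_force_cages(s, p):
    """Literal reading of the criteria: every same-chain subset of size >= 3
    of near-ligand aromatics, checked for (a), (b), (c) directly."""
    accepted = []
    for lig in extract_ligands(s):
        lig_xyz = lig.coords()
        by_chain = {}
        for r in candidate_residues(s, lig, p):
            by_chain.setdefault(r.chain_id, []).append(r)
        for rs in by_chain.values():
            for k in range(p.min_residues, len(rs) + 1):
                for sub in itertools.combinations(rs, k):
                    mcs = [side_chain_mass_center(r) for r in sub]
                    if any(np.linalg.norm(mcs[i] - mcs[j]) >= p.pair_center_max
                           for i in range(k) for j in range(i + 1, k)):
                        continue
                    mc = cage_center(sub)
                    if sum(normal_center_angle(r, mc) < p.angle_max
                           for r in sub) < 3:
                        continue
                    n_center = int(np.sum(
                        np.linalg.norm(lig_xyz - mc, axis=1) < p.center_contact_max))
                    if n_center < p.min_ligand_atoms_in_center:
                        continue
                    accepted.append((lig.id, frozenset(r.id for r in sub)))
    return accepted


@pytest.mark.parametrize("seed", range(12))
def test_oracle_equivalence_on_random_fixtures(seed, params):
    s = make_random_structure(seed)
    reported = [(c.ligand.id, frozenset(c.residue_ids)) for c in detect_cages(s)]
    accepted = brute_force_cages(s, params)
    for lid, sub in accepted:  # every accepted subset inside a reported cage
        assert any(lid == rl and sub <= rs for rl, rs in reported)
    accepted_set = set(accepted)
    for item in reported:      # every reported cage itself passes a-c
        assert item in accepted_set


def test_all_subsets_mode_equals_brute_force(params):
    s = make_random_structure(7)
    got = sorted((c.ligand.id, frozenset(c.residue_ids))
                 for c in detect_cages(s, mode="all-subsets"))
    assert got == sorted(brute_force_cages(s, params))


@pytest.mark.parametrize("loosen", [
    dict(angle_max=80.0),
    dict(pair_center_max=12.0),
    dict(ligand_contact_max=8.0),
])
def test_monotonicity_of_accepted_subsets(loosen):
    strict = DetectionParams()
    loose = DetectionParams(**loosen)
    for seed in (0, 1, 2):
        s = make_random_structure(seed)
        a = {(c.ligand.id, frozenset(c.residue_ids))
             for c in detect_cages(s, strict, mode="all-subsets")}
        b = {(c.ligand.id, frozenset(c.residue_ids))
             for c in detect_cages(s, loose, mode="all-subsets")}
        assert a <= b


class TestDedupAndGroup:
    def test_same_composition_deduplicated(self, planted_fixture):
        a = detect_cages(planted_fixture.structure)
        other = Structure(pdb_id="COPY", models=planted_fixture.structure.models)
        b = detect_cages(other)
        merged = deduplicate(a + b)
        assert len(merged) == 1 and merged[0].pdb_id == a[0].pdb_id

    def test_different_names_same_numbers_kept(self, planted_fixture):
        (cage,) = detect_cages(planted_fixture.structure)
        renamed = [Residue(name="TYR" if r.name == "PHE" else r.name,
                           chain_id=r.chain_id, seq_num=r.seq_num,
                           atoms=r.atoms) for r in cage.residues]
        other = Cage(pdb_id="X", ligand=cage.ligand, residues=tuple(renamed),
                     chain_id=cage.chain_id, mc_all=cage.mc_all,
                     angles_deg={r.id: 0.0 for r in renamed},
                     n_ligand_atoms_in_center=2, n_angle_satisfying=3)
        assert cage_key(cage) != cage_key(other)
        assert len(deduplicate([cage, other])) == 2

    def test_dedup_idempotent(self, planted_fixture):
        cages = detect_cages(planted_fixture.structure) * 3
        once = deduplicate(cages)
        assert deduplicate(once) == once

    def test_grouping_partitions(self):
        cages = []
        for seed, tmpl in [(1, "uracil"), (2, "uracil"), (3, "butane")]:
            st = make_cage_structure(CageFixtureSpec(
                ligand_template=tmpl, seed=seed,
                residue_types=("PHE", "TYR", "TRP")))
            cages.extend(detect_cages(st))
        groups = group_by_ligand(cages)
        assert {k: len(v) for k, v in groups.items()} == {"URA": 2, "BUT": 1}
        assert sum(len(v) for v in groups.values()) == len(cages)
        assert group_by_ligand([]) == {}
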