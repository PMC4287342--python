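"""Detect an aromatic cage in a synthetic structure with a planted cage.

Builds a structure in which three aromatic residues (Phe, Tyr, Trp) surround
a uracil-like ligand at 5 A with their ring normals 20 degrees off the
centre direction, then runs the geometric detector and prints what it found.
"""

from cagescan import CageFixtureSpec, detect_cages, make_cage_structure

structure = make_cage_structure(CageFixtureSpec(
    n_residues=3, residue_types=("PHE", "TYR", "TRP"),
    ring_radius=5.0, normal_tilt=20.0, ligand_template="uracil", seed=5))

for cage in detect_cages(structure):
    print(f"ligand {cage.ligand.comp_id} chain {cage.chain_id}:")
    for r in cage.residues:
        # angle between the ring normal and the vector to the cage centre;
        # a residue supports the cage when it is below 60 degrees
        print(f"  {r.name}{r.seq_num}: normal-to-centre angle "
              f"{cage.angles_deg[r.id]:.1f} deg")
    print(f"  ligand atoms within 3 A of the cage centre: "
          f"{cage.n_ligand_atoms_in_center}")
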