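"""Classify the cage-bound moiety of each exemplar ligand template.

For every built-in ligand template, a cage is planted around it and the
moiety inserted into the cage is assigned to one of the five classes:
heterocyclic ring, hydrocarbon ring, hydrocarbon chain with/without N,O,S,
or ammonium-based cation.
"""

from cagescan import (CageFixtureSpec, classify_ligand, detect_cages,
                      make_cage_structure)
from cagescan.synth import LIGAND_TEMPLATES

for template in sorted(LIGAND_TEMPLATES):
    structure = make_cage_structure(CageFixtureSpec(
        n_residues=3, residue_types=("PHE", "TYR", "TRP"),
        ring_radius=5.0, normal_tilt=20.0, ligand_template=template, seed=11))
    (cage,) = detect_cages(structure)
    category = classify_ligand(cage.ligand, cage)
    print(f"{template:20s} ({cage.ligand.comp_id}) -> {category.value}")
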