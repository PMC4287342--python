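"""Batch-scan a small corpus of PDB files and summarise the cages.

Writes three synthetic structures to a temporary directory (two contain the
same cage composition binding the same ligand, so they deduplicate to one),
scans them, and prints the aggregate report: total cages, unique cages
after removing identical residue-name/number compositions per ligand,
ligand groups and the category histogram.
"""

import tempfile
from pathlib import Path

from cagescan import CageFixtureSpec, make_cage_structure, run_scan, write_pdb

specs = {
    "site_a": CageFixtureSpec(residue_types=("PHE", "TYR", "TRP"),
                              normal_tilt=20.0, ligand_template="uracil", seed=1),
    "site_a_again": CageFixtureSpec(residue_types=("PHE", "TYR", "TRP"),
                                    normal_tilt=20.0, ligand_template="uracil",
                                    seed=1),
    "site_b": CageFixtureSpec(residue_types=("TRP", "TRP", "TRP"),
                              normal_tilt=10.0,
                              ligand_template="trimethylammonium", seed=2),
}

with tempfile.TemporaryDirectory() as tmp:
    paths = []
    for name, spec in specs.items():
        p = Path(tmp) / f"{name}.pdb"
        p.write_text(write_pdb(make_cage_structure(spec)))
        paths.append(p)
    report = run_scan(paths)

for key, value in report.summary().items():
    print(f"{key}: {value}")
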