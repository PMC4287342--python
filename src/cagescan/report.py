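"""Batch scanning and reporting: scan -> deduplicate -> group -> classify.

Aggregates cage detection over a corpus of PDB files into a tabular report
(TSV and JSON carry identical cage sets) plus summary statistics: total
cages, unique cages after the composite-name/number deduplication, ligand
group count, and the category histogram over unique cages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chem import LigandCategory, classify_ligand
from .detect import Cage, DetectionParams, cage_key, deduplicate, detect_cages
from .detect import group_by_ligand
from .structure import PDBParseError, parse_pdb_file

logger = logging.getLogger("cagescan")

__all__ = ["ScanReport", "run_scan", "TSV_COLUMNS"]

TSV_COLUMNS = [
    "pdb_id", "ligand_comp_id", "ligand_chain", "ligand_seq", "cage_chain",
    "residues", "angles_deg", "n_center_atoms", "category",
]


@dataclass
class ScanReport:
    cages: list[Cage]
    categories: list[LigandCategory]
    params: DetectionParams
    n_structures: int
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (path, reason)

    @property
    def unique_cages(self) -> list[Cage]:
        return deduplicate(self.cages)

    def summary(self) -> dict:
        unique = self.unique_cages
        unique_keys = {cage_key(c) for c in unique}
        hist: dict[str, int] = {}
        seen = set()
        for c, cat in zip(self.cages, self.categories):
            k = cage_key(c)
            if k in unique_keys and k not in seen:
                seen.add(k)
                hist[cat.value] = hist.get(cat.value, 0) + 1
        return {
            "n_structures": self.n_structures,
            "n_skipped": len(self.skipped),
            "n_cages": len(self.cages),
            "n_unique_cages": len(unique),
            "n_ligand_groups": len(group_by_ligand(unique)),
            "category_histogram": dict(sorted(hist.items())),
        }

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c, cat in zip(self.cages, self.categories):
            rows.append({
                "pdb_id": c.pdb_id,
                "ligand_comp_id": c.ligand.comp_id,
                "ligand_chain": c.ligand.chain_id,
                "ligand_seq": c.ligand.seq_num,
                "cage_chain": c.chain_id,
                "residues": ";".join(c.residue_labels()),
                "angles_deg": ";".join(f"{c.angles_deg[r.id]:.1f}" for r in c.residues),
                "n_center_atoms": c.n_ligand_atoms_in_center,
                "category": cat.value,
            })
        df = pd.DataFrame(rows, columns=TSV_COLUMNS)
        return df.sort_values(TSV_COLUMNS[:6]).reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_json_dict(self) -> dict:
        return {
            "params": {
                "ligand_contact_max": self.params.ligand_contact_max,
                "pair_center_max": self.params.pair_center_max,
                "angle_max": self.params.angle_max,
                "center_contact_max": self.params.center_contact_max,
                "min_residues": self.params.min_residues,
                "min_ligand_atoms_in_center": self.params.min_ligand_atoms_in_center,
            },
            "summary": self.summary(),
            "skipped": [{"path": p, "reason": r} for p, r in self.skipped],
            "cages": self.to_dataframe().to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1) + "\n")


def run_scan(paths, params: DetectionParams | None = None,
             model_index: int = 0, classify: bool = True,
             mode: str = "maximal") -> ScanReport:
    """Scan a corpus of PDB files for ligand-binding aromatic cages.

    Unreadable or unparseable files are skipped with a warning and recorded
    in ``report.skipped``; the remaining files are still processed.  Report
    statistics do not depend on file order.
    """
    import time

    params = params or DetectionParams()
    cages: list[Cage] = []
    cats: list[LigandCategory] = []
    skipped: list[tuple[str, str]] = []
    n_ok = 0
    for path in paths:
        t0 = time.perf_counter()
        try:
            s = parse_pdb_file(path)
        except (OSError, PDBParseError) as e:
            logger.warning("skipping %s: %s", path, e)
            skipped.append((str(path), str(e)))
            continue
        found = detect_cages(s, params, model_index=model_index, mode=mode)
        for c in found:
            cages.append(c)
            cats.append(classify_ligand(c.ligand, c) if classify
                        else LigandCategory.UNCLASSIFIED)
        n_ok += 1
        logger.info("%s: %d cage(s) in %.3f s", path, len(found),
                    time.perf_counter() - t0)
    return ScanReport(cages=cages, categories=cats, params=params,
                      n_structures=n_ok, skipped=skipped)
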