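"""PDB structure handling: parsing, writing and candidate-ligand extraction.

The scan treats every non-water HETATM residue group as a candidate ligand,
so the in-memory model keeps the ATOM/HETATM distinction, alternate-location
collapse and the heavy-atom convention front and centre.  Record-level
parsing is delegated to :mod:`gemmi`; the hierarchy exposed here is a small,
immutable-ish view tailored to the geometric criteria downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "LigandInstance",
    "PDBParseError",
    "PDBWriteError",
    "parse_pdb",
    "parse_pdb_file",
    "write_pdb",
    "extract_ligands",
    "WATER_NAMES",
    "BACKBONE_ATOMS",
]

#: Residue names treated as water and never considered ligands.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: Backbone heavy atoms excluded from every side-chain computation.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


class PDBWriteError(ValueError):
    """Raised when a structure cannot be represented in fixed-width PDB."""


@dataclass(frozen=True)
class Atom:
    """One heavy or hydrogen atom with its PDB identity and position."""

    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    alt_loc: str = ""
    is_hetatm: bool = False

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def mass(self) -> float:
        el = gemmi.Element(self.element)
        if el.name == "X" or el.weight <= 0:
            raise ValueError(f"atom {self.name!r}: element {self.element!r} has no standard mass")
        return el.weight

    def moved(self, coords: np.ndarray) -> "Atom":
        return Atom(self.serial, self.name, self.element, np.asarray(coords, float),
                    self.occupancy, self.alt_loc, self.is_hetatm)


@dataclass
class Residue:
    """A residue (polymer or het group) identified by (chain, seq, icode, name)."""

    name: str
    chain_id: str
    seq_num: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def id(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.seq_num, self.insertion_code, self.name)

    @property
    def is_hetatm(self) -> bool:
        return bool(self.atoms) and all(a.is_hetatm for a in self.atoms)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def side_chain_atoms(self) -> list[Atom]:
        """Heavy atoms excluding the peptide backbone (N, CA, C, O, OXT)."""
        return [a for a in self.heavy_atoms() if a.name not in BACKBONE_ATOMS]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name} {self.chain_id}{self.seq_num}: no atom {name!r}")

    def coords(self, names: Sequence[str] | None = None) -> np.ndarray:
        if names is None:
            return np.array([a.coords for a in self.atoms], float)
        return np.array([self.atom(n).coords for n in names], float)


@dataclass(frozen=True)
class LigandInstance:
    """One non-water HETATM residue group regarded as a candidate ligand.

    Carries heavy atoms only; hydrogens never enter distances or mass centres.
    """

    comp_id: str
    chain_id: str
    seq_num: int
    insertion_code: str
    atoms: tuple[Atom, ...]

    @property
    def id(self) -> tuple[str, str, int, str]:
        return (self.comp_id, self.chain_id, self.seq_num, self.insertion_code)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], float)


@dataclass
class Structure:
    """Parsed structure: ordered models, each a list of residues."""

    pdb_id: str
    models: list[list[Residue]]
    header_date: str | None = None

    def residues(self, model_index: int = 0) -> list[Residue]:
        try:
            return self.models[model_index]
        except IndexError:
            raise IndexError(
                f"{self.pdb_id}: model index {model_index} out of range "
                f"({len(self.models)} model(s))"
            ) from None

    def chains(self, model_index: int = 0) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for r in self.residues(model_index):
            out.setdefault(r.chain_id, []).append(r)
        return out


# ---------------------------------------------------------------------------
# parsing

def _validate_records(text: str) -> int:
    """Pre-flight check of fixed-width ATOM/HETATM records; returns record count."""
    n = 0
    for i, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        n += 1
        if len(line) < 54:
            raise PDBParseError(f"line {i}: truncated {rec} record ({len(line)} columns)")
        try:
            float(line[30:38]), float(line[38:46]), float(line[46:54])
        except ValueError:
            raise PDBParseError(f"line {i}: unparseable coordinates in {rec} record") from None
        try:
            int(line[22:26])
        except ValueError:
            raise PDBParseError(f"line {i}: unparseable residue number in {rec} record") from None
    return n


def _collapse_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep the highest-occupancy conformer per atom name (ties: first seen)."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [best[n] for n in order]


def parse_pdb(text: str, pdb_id: str = "XXXX") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Alternate locations are collapsed to the highest-occupancy conformer per
    atom name.  Hydrogens are retained (flagged by element).  Raises
    :class:`PDBParseError` for empty input or malformed fixed-width records,
    naming the offending line.
    """
    if not text or not text.strip():
        raise PDBParseError("empty PDB input")
    if _validate_records(text) == 0:
        raise PDBParseError("no ATOM or HETATM records in input")
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as e:  # pragma: no cover - gemmi is lenient
        raise PDBParseError(str(e)) from e

    models: list[list[Residue]] = []
    for model in st:
        residues: list[Residue] = []
        for chain in model:
            for res in chain:
                atoms = []
                for at in res:
                    el = at.element.name
                    atoms.append(Atom(
                        serial=at.serial,
                        name=at.name,
                        element="X" if el == "X" else el,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z], float),
                        occupancy=at.occ,
                        alt_loc=at.altloc if at.altloc != "\x00" else "",
                        is_hetatm=res.het_flag == "H",
                    ))
                residues.append(Residue(
                    name=res.name,
                    chain_id=chain.name,
                    seq_num=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    atoms=_collapse_altlocs(atoms),
                ))
        models.append(residues)
    date = None
    for line in text.splitlines():
        if line.startswith("HEADER") and len(line) >= 59:
            date = line[50:59].strip() or None
            break
    name = (st.name or "").strip()
    if len(name) == 4:
        pdb_id = name.upper() if pdb_id == "XXXX" else pdb_id
    return Structure(pdb_id=pdb_id, models=models, header_date=date or None)


def parse_pdb_file(path) -> Structure:
    import pathlib

    p = pathlib.Path(path)
    return parse_pdb(p.read_text(), pdb_id=p.stem[:8].upper())


# ---------------------------------------------------------------------------
# writing

def _format_atom_name(name: str, element: str) -> str:
    # Column-13 convention: 1-char elements indent single-letter-led names.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_pdb(s: Structure) -> str:
    """Serialise to fixed-width PDB v3.3 ATOM/HETATM/MODEL/ENDMDL/TER records.

    Coordinates outside the representable %8.3f field raise
    :class:`PDBWriteError`.  ``parse_pdb(write_pdb(s))`` reproduces atom
    names, residue identities and coordinates to three decimals.
    """
    lines: list[str] = []
    multi = len(s.models) > 1
    for mi, residues in enumerate(s.models, start=1):
        if multi:
            lines.append(f"MODEL     {mi:4d}")
        serial = 0
        prev_chain: str | None = None
        prev_polymer = False
        for res in residues:
            is_het = res.is_hetatm
            if prev_chain is not None and res.chain_id != prev_chain and prev_polymer:
                lines.append("TER")
            for a in res.atoms:
                serial += 1
                x, y, z = (float(v) for v in a.coords)
                for v in (x, y, z):
                    if not math.isfinite(v) or not (-999.999 <= v <= 9999.999):
                        raise PDBWriteError(
                            f"coordinate {v} of atom {a.name} in {res.name} "
                            f"{res.chain_id}{res.seq_num} does not fit PDB fixed width"
                        )
                rec = "HETATM" if a.is_hetatm else "ATOM"
                lines.append(
                    f"{rec:<6s}{serial % 100000:5d} {_format_atom_name(a.name, a.element)}"
                    f"{a.alt_loc or ' ':1s}{res.name:>3s} {res.chain_id[:1] or 'A':1s}"
                    f"{res.seq_num:4d}{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}"
                )
            prev_chain = res.chain_id
            prev_polymer = not is_het
        if prev_polymer:
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# ligand extraction

def extract_ligands(s: Structure, model_index: int = 0) -> list[LigandInstance]:
    """All non-water HETATM residue groups of one model, heavy atoms only.

    Modified residues present as HETATM within a polymer chain (e.g.
    trimethyllysine in a peptide) count as ligands, mirroring the scan's
    HETATM-record definition of the ligand universe.
    """
    out: list[LigandInstance] = []
    for res in s.residues(model_index):
        if not res.is_hetatm or res.is_water:
            continue
        heavy = tuple(res.heavy_atoms())
        if not heavy:
            continue
        out.append(LigandInstance(
            comp_id=res.name,
            chain_id=res.chain_id,
            seq_num=res.seq_num,
            insertion_code=res.insertion_code,
            atoms=heavy,
        ))
    return out
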