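"""Sequence and coordinate I/O.

Reads multi-record FASTA files and PDB coordinate files into a small
domain model (:class:`ProteinRecord` for sequences, :class:`Structure`
/ :class:`Chain` / :class:`Residue` / :class:`Atom` for coordinates in
ångström) and extracts per-chain one-letter sequences so that sequence
and structural stages operate on the same residues.

Parsing policies for crystallographic bookkeeping:

* only the first MODEL of a multi-model entry is kept;
* alternate locations are resolved to the highest-occupancy conformer
  (ties broken by file order);
* waters and non-amino-acid HETATM residues are excluded from chains,
  while modified amino acids recorded as HETATM (e.g. selenomethionine)
  are retained;
* the resolution is taken from the header when present.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import gemmi
import numpy as np
from Bio import SeqIO

from .errors import FastaFormatError, MissingChainError, PDBParseError

__all__ = [
    "ProteinRecord",
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "read_fasta",
    "write_fasta",
    "read_pdb",
    "parse_pdb_text",
    "write_pdb",
    "chain_sequence",
    "three_to_one",
    "AA3_TO_1",
    "AA1_TO_3",
]

#: Sequence alphabet: the 20 standard residues plus X for unknowns.
SEQUENCE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",  # selenomethionine maps to Met
}

AA1_TO_3 = {v: k for k, v in AA3_TO_1.items() if k != "MSE"}


@dataclass(frozen=True)
class ProteinRecord:
    """A named protein sequence over the 20 standard residues plus X."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaFormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise FastaFormatError(
                f"record {self.id!r}: illegal characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class Residue:
    name: str
    seq_number: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    resolution: Optional[float] = None  # Å

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise MissingChainError(
            f"structure {self.id!r} has no chain {chain_id!r} "
            f"(available: {[c.id for c in self.chains]})"
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: Union[str, Path]) -> list[ProteinRecord]:
    """Read a multi-record FASTA file.

    Sequences are uppercased; any character outside the 20-letter amino
    acid alphabet plus ``X`` raises :class:`FastaFormatError`. An empty
    file yields an empty list; non-FASTA text raises.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return []
    if not text.lstrip().startswith(">"):
        raise FastaFormatError(f"{path}: does not start with a FASTA header")
    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper().replace("*", "")
        records.append(
            ProteinRecord(id=rec.id, sequence=seq, description=rec.description)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: Union[str, Path],
                width: int = 60) -> None:
    lines = []
    for rec in records:
        desc = rec.description
        if desc and not desc.startswith(rec.id):
            header = f"{rec.id} {desc}"
        else:
            header = desc or rec.id
        lines.append(f">{header}")
        for i in range(0, len(rec.sequence), width):
            lines.append(rec.sequence[i:i + width])
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PDB


def _is_amino_acid(resname: str) -> bool:
    info = gemmi.find_tabulated_residue(resname)
    return bool(info and info.is_amino_acid())


def _convert_residue(res: gemmi.Residue) -> Residue:
    # altLoc resolution: highest occupancy wins, file order breaks ties
    chosen: dict[str, Atom] = {}
    for atom in res:
        pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        cand = Atom(
            name=atom.name,
            element=atom.element.name,
            position=pos,
            occupancy=float(atom.occ),
        )
        prev = chosen.get(atom.name)
        if prev is None or cand.occupancy > prev.occupancy:
            chosen[atom.name] = cand
    icode = res.seqid.icode.strip()
    return Residue(
        name=res.name,
        seq_number=res.seqid.num,
        insertion_code=icode,
        atoms=list(chosen.values()),
    )


def _convert_structure(st: gemmi.Structure, name: str) -> Structure:
    if len(st) == 0:
        raise PDBParseError(f"{name}: no coordinate model found")
    model = st[0]  # first-model policy
    chains: list[Chain] = []
    for gchain in model:
        residues = []
        for res in gchain:
            if res.is_water():
                continue
            if res.het_flag == "H" and not _is_amino_acid(res.name):
                continue  # ligands/ions stay out of the chain
            residues.append(_convert_residue(res))
        if residues:
            residues.sort(key=lambda r: (r.seq_number, r.insertion_code))
            chains.append(Chain(id=gchain.name, residues=residues))
    if not chains or all(len(c) == 0 for c in chains):
        raise PDBParseError(f"{name}: no ATOM records for amino-acid residues")
    resolution = float(st.resolution) if st.resolution else None
    return Structure(id=name or st.name, chains=chains, resolution=resolution)


def read_pdb(path: Union[str, Path]) -> Structure:
    """Parse a PDB file (first model, altLocs resolved, waters excluded)."""
    path = Path(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    return _convert_structure(st, name=path.stem)


def parse_pdb_text(text: str, name: str = "structure") -> Structure:
    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    return _convert_structure(st, name=name)


def write_pdb(structure: Structure) -> str:
    """Serialize a Structure to PDB-format text (ATOM records only)."""
    lines = []
    if structure.resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION. {structure.resolution:7.2f} ANGSTROMS."
        )
    serial = 0
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.position
                name = atom.name
                # PDB column rules: 1-3 char names start in column 14
                padded = f" {name:<3s}" if len(name) < 4 else name
                atom_icode = res.insertion_code or " "
                lines.append(
                    f"ATOM  {serial:5d} {padded:<4s} {res.name:<3s} "
                    f"{chain.id:1s}{res.seq_number:4d}{atom_icode:1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        serial += 1
        lines.append(f"TER   {serial:5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def three_to_one(resname: str) -> str:
    """Map a 3-letter residue code to one letter (MSE→M, unknown→X)."""
    code = AA3_TO_1.get(resname.upper())
    if code is not None:
        return code
    info = gemmi.find_tabulated_residue(resname.upper())
    if info and info.is_amino_acid():
        one = info.one_letter_code.upper()
        if one.isalpha() and one in SEQUENCE_ALPHABET:
            return one
    return "X"


def chain_sequence(structure: Structure, chain_id: str) -> ProteinRecord:
    """One-letter sequence of a chain, in residue order.

    Length equals the number of residues in the chain; unrecognised
    residues appear as ``X`` so coordinates and sequence stay in
    register for alignment-guided superposition.
    """
    chain = structure.chain(chain_id)
    seq = "".join(three_to_one(r.name) for r in chain.residues)
    return ProteinRecord(
        id=f"{structure.id}_{chain_id}",
        sequence=seq,
        description=f"{structure.id} chain {chain_id}",
    )
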