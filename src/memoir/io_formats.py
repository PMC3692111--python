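"""Structure and sequence I/O: PDB, FASTA and gapped-FASTA alignments.

The pipeline operates on a deliberately small structural model: a
:class:`Structure` is an ordered list of chains of residues, each residue a
map from atom name to coordinates plus its author numbering.  PDB parsing is
delegated to gemmi; writing uses a fixed-column writer so the output contract
(serials from 1, TER per chain, END last) is exact and round trips are
bit-stable to three decimals.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio import SeqIO

from ._tables import ONE_TO_THREE, THREE_TO_ONE

__all__ = [
    "FormatError", "Residue", "Chain", "Structure", "SequenceRecord",
    "read_pdb", "write_pdb", "read_fasta", "write_fasta",
    "write_alignment", "read_alignment",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
_VALID_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX")


class FormatError(ValueError):
    """Raised for unreadable or unwritable structure/sequence files."""


@dataclass
class Residue:
    name: str
    number: int
    icode: str = ""
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def has_complete_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    def copy(self) -> "Residue":
        return Residue(self.name, self.number, self.icode,
                       {k: np.array(v, dtype=float) for k, v in self.atoms.items()})


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str | None = None) -> Chain:
        if chain_id is None:
            return self.chains[0]
        for ch in self.chains:
            if ch.id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    def sequence(self, chain_id: str | None = None) -> str:
        return self.chain(chain_id).sequence

    def copy(self) -> "Structure":
        return Structure(self.id, [Chain(c.id, [r.copy() for r in c.residues])
                                   for c in self.chains])


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise FormatError(f"empty sequence for record {self.id!r}")
        if "-" in self.sequence:
            raise FormatError(
                f"aligned input not allowed here: record {self.id!r} contains gaps")

    def __len__(self) -> int:
        return len(self.sequence)


def _clean_sequence(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace("*", "")
    if "-" in seq or "." in seq:
        raise FormatError(
            f"aligned input not allowed here: record {rec_id!r} contains gap characters")
    if not seq:
        raise FormatError(f"empty sequence for record {rec_id!r}")
    out = []
    for ch in seq:
        if ch in _VALID_LETTERS:
            out.append(ch)
        elif ch.isalpha():
            out.append("X")  # B/Z/U/O and friends
        else:
            raise FormatError(f"invalid character {ch!r} in record {rec_id!r}")
    return "".join(out)


def read_fasta(path) -> list[SequenceRecord]:
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, _clean_sequence(str(rec.seq), rec.id)))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# PDB

def read_pdb(path, structure_id: str | None = None) -> Structure:
    """Read a PDB file, keeping one conformer per residue.

    For alternate locations the highest-occupancy conformer wins (ties: first
    in file).  HETATM records are dropped, except selenomethionine (MSE),
    which is read as methionine.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"malformed record in {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"empty structure: no ATOM records in {path}")
    model = st[0]
    chains: list[Chain] = []
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            name = res.name
            if res.het_flag == "H" and name != "MSE":
                continue
            if name == "MSE":
                name = "MET"
            atoms: dict[str, np.ndarray] = {}
            occ: dict[str, float] = {}
            for atom in res:
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if not np.isfinite(pos).all():
                    raise FormatError(
                        f"malformed record: non-finite coordinate in {path}")
                if atom.name not in atoms or atom.occ > occ[atom.name]:
                    atoms[atom.name] = pos
                    occ[atom.name] = atom.occ
            if atoms:
                icode = res.seqid.icode.strip()
                residues.append(Residue(name, res.seqid.num, icode, atoms))
        if residues:
            chains.append(Chain(ch.name, residues))
    if not chains:
        raise FormatError(f"empty structure: no ATOM records in {path}")
    return Structure(structure_id or path.stem, chains)


def _element_of(atom_name: str) -> str:
    stripped = atom_name.lstrip("0123456789")
    return stripped[0] if stripped else "C"


_ATOM_ORDER = {"N": 0, "CA": 1, "C": 2, "O": 3, "CB": 4}


def _sorted_atoms(res: Residue):
    order = {n: i for i, n in enumerate(res.atoms)}
    names = sorted(res.atoms, key=lambda n: (_ATOM_ORDER.get(n, 5), order[n]))
    return [(n, res.atoms[n]) for n in names]


def write_pdb(structure: Structure, path) -> None:
    """Write fixed-column ATOM records, serials from 1, TER per chain, END."""
    lines: list[str] = []
    serial = 0
    for ch in structure.chains:
        last = None
        for res in ch.residues:
            if not res.atoms:
                raise FormatError(
                    f"unwritable residue {res.name} {res.number}{res.icode}: no atoms")
            for atom_name, xyz in _sorted_atoms(res):
                serial += 1
                name_field = f" {atom_name:<3}" if len(atom_name) < 4 else atom_name
                lines.append(
                    f"ATOM  {serial:5d} {name_field} {res.name:>3} {ch.id[:1] or 'A'}"
                    f"{res.number:4d}{res.icode or ' ':1}   "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {_element_of(atom_name):>2}"
                )
            last = res
        if last is not None:
            serial += 1
            lines.append(
                f"TER   {serial:5d}      {last.name:>3} {ch.id[:1] or 'A'}"
                f"{last.number:4d}{last.icode or ' ':1}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Gapped-FASTA alignments with optional per-row annotation tracks.
#
# Dialect: each record is ">id" followed by a single line holding the gapped
# row; an optional line "#= <id>" followed by one line carries a per-column
# annotation track ('-' on that row's gap columns).

def write_alignment(rows: dict[str, str], path, tracks: dict[str, str] | None = None) -> None:
    rows = dict(rows)
    widths = {len(r) for r in rows.values()}
    if len(widths) > 1:
        raise FormatError(f"inconsistent alignment width: {sorted(widths)}")
    tracks = tracks or {}
    with open(path, "w") as fh:
        for rid, row in rows.items():
            fh.write(f">{rid}\n{row}\n")
            if rid in tracks:
                track = tracks[rid]
                if len(track) != len(row):
                    raise FormatError(
                        f"annotation track length {len(track)} != width {len(row)}")
                fh.write(f"#= {rid}\n{track}\n")


def read_alignment(path) -> tuple[dict[str, str], dict[str, str]]:
    rows: dict[str, str] = {}
    tracks: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith(">"):
            rows[line[1:].split()[0]] = lines[i + 1].strip()
            i += 2
        elif line.startswith("#="):
            tracks[line[2:].strip()] = lines[i + 1].strip()
            i += 2
        else:
            i += 1
    widths = {len(r) for r in rows.values()}
    if len(widths) > 1:
        raise FormatError(f"inconsistent alignment width: {sorted(widths)}")
    return rows, tracks


def residue_from_letter(letter: str, number: int) -> Residue:
    """Convenience: an empty residue of the 3-letter type for a sequence letter."""
    return Residue(ONE_TO_THREE.get(letter, "UNK"), number)
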