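"""Reading and writing of fixed-column PDB coordinate files and FASTA sequences.

Only ATOM records of the 20 standard amino acids are retained; HETATM,
waters and nucleic acids never enter the analysis.  The reader reports
malformed ATOM lines with their line number and resolves alternate
locations by a caller-chosen policy.  Author residue numbering is kept
verbatim; the package never renumbers.
"""
from __future__ import annotations

import io
from pathlib import Path

from Bio import SeqIO

from .model import (
    Atom,
    Chain,
    Residue,
    STANDARD_RESIDUES,
    Structure,
    THREE_TO_ONE,
    element_from_name,
)

ALTLOC_POLICIES = ("highest_occupancy", "first")


class PDBParseError(ValueError):
    """Malformed PDB content; message carries the 1-based line number."""


class EmptyStructureError(ValueError):
    """A coordinate file with no usable ATOM records."""


def _parse_atom_line(line: str, lineno: int) -> tuple[str, str, int, str, Atom]:
    # Fixed columns per the PDB v3 ATOM record definition.
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: ATOM record shorter than coordinate fields")
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip().upper()
        chain_id = line[21].strip() or "A"
        resseq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM record ({exc})") from None
    if not element:
        element = element_from_name(name)
    atom = Atom(name=name, element=element, coords=(x, y, z),
                occupancy=occupancy, altloc=altloc)
    return chain_id, resname, resseq, icode, atom


def _resolve_altlocs(atoms: list[Atom], policy: str) -> list[Atom]:
    """Keep one atom per name.  highest_occupancy breaks ties by altloc letter."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    resolved = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            chosen = group[0]
        elif policy == "first":
            chosen = group[0]
        else:  # highest_occupancy
            chosen = min(group, key=lambda a: (-a.occupancy, a.altloc))
        resolved.append(chosen)
    return resolved


def parse_pdb(path: str | Path, altloc_policy: str = "highest_occupancy") -> Structure:
    """Parse a PDB file into a Structure of standard-amino-acid chains.

    Parameters
    ----------
    path
        Coordinate file with at least one ATOM record.
    altloc_policy
        ``highest_occupancy`` (ties broken by altloc letter) or ``first``.
    """
    if altloc_policy not in ALTLOC_POLICIES:
        raise ValueError(f"altloc_policy must be one of {ALTLOC_POLICIES}")
    path = Path(path)
    text = path.read_text()

    # chain id -> residue key -> (resname, [atoms]); insertion order preserved
    chains: dict[str, dict[tuple[int, str], tuple[str, list[Atom]]]] = {}
    n_atom_records = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record != "ATOM":
            continue  # HETATM (waters, ligands, MSE) and everything else excluded
        n_atom_records += 1
        chain_id, resname, resseq, icode, atom = _parse_atom_line(line, lineno)
        if resname not in STANDARD_RESIDUES:
            continue
        residues = chains.setdefault(chain_id, {})
        key = (resseq, icode)
        if key not in residues:
            residues[key] = (resname, [])
        residues[key][1].append(atom)

    if n_atom_records == 0:
        raise EmptyStructureError(f"{path}: no ATOM records")

    structure = Structure(source=str(path))
    for chain_id, residues in chains.items():
        chain = Chain(id=chain_id)
        for (resseq, icode), (resname, atoms) in residues.items():
            chain.residues.append(
                Residue(name=resname, number=resseq, icode=icode,
                        atoms=_resolve_altlocs(atoms, altloc_policy))
            )
        chain = chain.sorted()
        chain.validate()
        structure.chains.append(chain)
    structure.validate()
    return structure


def format_atom_name(name: str, element: str) -> str:
    """Place an atom name in PDB columns 13-16 (element right-aligned in 13-14)."""
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write fixed-column ATOM/TER/END records; round-trips through parse_pdb."""
    if not structure.chains or all(len(c) == 0 for c in structure.chains):
        raise ValueError("refusing to write an empty structure")
    lines = []
    serial = 0
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.coords
                lines.append(
                    "ATOM  {serial:>5d} {name}{altloc:1s}{resname:>3s} {chain:1s}"
                    "{resseq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
                    "          {element:>2s}".format(
                        serial=serial,
                        name=format_atom_name(atom.name, atom.element),
                        altloc=atom.altloc or " ",
                        resname=res.name,
                        chain=chain.id[:1] or "A",
                        resseq=res.number,
                        icode=res.icode or " ",
                        x=x, y=y, z=z,
                        occ=atom.occupancy, b=0.0,
                        element=atom.element,
                    )
                )
        serial += 1
        last = chain.residues[-1]
        lines.append(
            "TER   {serial:>5d}      {resname:>3s} {chain:1s}{resseq:>4d}{icode:1s}".format(
                serial=serial, resname=last.name, chain=chain.id[:1] or "A",
                resseq=last.number, icode=last.icode or " ")
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def extract_sequence(chain: Chain) -> str:
    """1-letter sequence of a chain; errors on any non-standard residue."""
    letters = []
    bad = []
    for res in chain.residues:
        letter = THREE_TO_ONE.get(res.name)
        if letter is None:
            bad.append(f"{res.name}{res.number}{res.icode}")
        else:
            letters.append(letter)
    if bad:
        raise ValueError(f"chain {chain.id!r}: non-standard residues {', '.join(bad)}")
    return "".join(letters)


def parse_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (header, uppercased sequence) pairs in file order."""
    text = Path(path).read_text()
    stripped = text.strip()
    if stripped and not stripped.startswith(">"):
        raise ValueError(f"{path}: sequence data before first FASTA header")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        records.append((rec.description, str(rec.seq).upper().replace(" ", "")))
    return records
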