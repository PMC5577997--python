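"""Hierarchical coordinate model: Structure -> Chain -> Residue -> Atom.

Coordinates are in Angstrom throughout.  Residue numbering is always the
author numbering from the input file; nothing in the package renumbers.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

#: The twenty standard amino acids, 3-letter -> 1-letter.
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_RESIDUES = frozenset(THREE_TO_ONE)


def element_from_name(name: str) -> str:
    """Derive the element symbol from a PDB atom name (digits stripped)."""
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        return ""
    # Two-letter elements in amino acids are absent (Se only in MSE, excluded);
    # the leading letter is the element for all standard protein atoms.
    return stripped[0].upper()


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.name!r}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: non-finite coordinates")

    def distance(self, other: "Atom") -> float:
        return float(math.dist(self.coords, other.coords))


@dataclass
class Residue:
    name: str
    number: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)
    species_tag: str = ""
    subunit_tag: str = "other"

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def sorted(self) -> "Chain":
        """Return a copy with residues ordered by (number, icode)."""
        return replace(self, residues=sorted(self.residues, key=lambda r: r.key))

    def validate(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"chain {self.id!r}: duplicated residue keys {dupes}")


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    source: str = ""

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.source!r}")

    def validate(self) -> None:
        ids = [c.id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids in structure {self.source!r}")
        for c in self.chains:
            c.validate()


def transform(structure: Structure, rotation: np.ndarray, translation: np.ndarray) -> Structure:
    """Apply a rigid motion (rotation matrix + translation vector) to every atom."""
    rot = np.asarray(rotation, dtype=float)
    tr = np.asarray(translation, dtype=float)
    chains = []
    for ch in structure.chains:
        residues = []
        for res in ch.residues:
            atoms = [replace(a, coords=rot @ a.coords + tr) for a in res.atoms]
            residues.append(replace(res, atoms=atoms))
        chains.append(replace(ch, residues=residues))
    return replace(structure, chains=chains)
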